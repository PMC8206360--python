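"""Cohort selection, F_ROH ANOVA, descriptive statistics and orchestration.

The cohort filters reproduce a breed-association sampling design: keep only
animals with a defined production subgroup (filter 1), genotyped on a
sufficiently dense chip (filter 2), born inside a fixed year range
(filter 3), then drop sparsely genotyped herd-years, cap the animals drawn
per herd within subgroup, and finally draw a fixed number per subgroup at
random (filter 4).  All random draws are seeded.

``run_pipeline`` sequences the stages: cohort -> QC -> ROH branch (full
post-QC panel) and structure branch (LD-pruned panel), writing tidy TSV/JSON
artifacts and a run log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .plink import GenotypeDataset, read_plink_binary, read_plink_text
from .qc import QCThresholds, LDPruneParams, apply_qc, ld_prune
from .roh import (ROHParams, detect_roh, segments_to_frame, froh_table,
                  roh_summary, consensus_regions, consensus_to_frame)
from .simulate import SimParams, simulate_herd_cohort
from .structure import (pca_genotypes, kmeans_bic_scan, dapc_fit, dapc_predict,
                        reassignment_accuracy, pairwise_validation_matrix)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortFilters:
    allowed_subgroups: tuple[str, ...] = ("AS", "DM", "GP", "PR", "TR")
    min_panel_density: int = 50_000
    birth_year_range: tuple[int, int] = (2014, 2018)
    min_genotyped_per_herd_year: int = 10
    max_per_herd_subgroup: int = 10
    n_target_per_subgroup: int = 200
    seed: int = 0


def select_cohort(metadata: pd.DataFrame, filters: CohortFilters = CohortFilters()
                  ) -> tuple[list[str], pd.DataFrame]:
    """Apply the four sampling filters; return (sample ids, attrition table).

    The attrition table counts survivors per subgroup after each filter and
    after the final per-subgroup draw.  Herd-year sparsity is judged on the
    animals surviving filter 3; the per-herd cap and the final draw are
    seeded random samples.
    """
    rng = np.random.default_rng(filters.seed)
    df = metadata.copy()
    stages: dict[str, pd.Series] = {}

    df = df[df["subgroup"].isin(filters.allowed_subgroups) & df["subgroup"].notna()]
    stages["filter1_subgroup"] = df["subgroup"].value_counts()
    df = df[df["panel_density"] >= filters.min_panel_density]
    stages["filter2_panel"] = df["subgroup"].value_counts()
    lo, hi = filters.birth_year_range
    df = df[(df["birth_year"] >= lo) & (df["birth_year"] <= hi)]
    stages["filter3_birth_year"] = df["subgroup"].value_counts()

    herd_year_sizes = df.groupby(["herd_id", "birth_year"])["sample_id"].transform("size")
    df = df[herd_year_sizes >= filters.min_genotyped_per_herd_year]

    def cap(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) <= filters.max_per_herd_subgroup:
            return group
        take = rng.choice(len(group), size=filters.max_per_herd_subgroup,
                          replace=False)
        return group.iloc[np.sort(take)]

    keep_mask = pd.Series(False, index=df.index)
    for _, group in df.groupby(["herd_id", "subgroup"], sort=True):
        if len(group) <= filters.max_per_herd_subgroup:
            keep_mask[group.index] = True
        else:
            take = rng.choice(len(group), size=filters.max_per_herd_subgroup,
                              replace=False)
            keep_mask[group.index[np.sort(take)]] = True
    df = df[keep_mask]
    stages["filter4_herd"] = df["subgroup"].value_counts()

    selected = []
    for sg in filters.allowed_subgroups:
        pool = df[df["subgroup"] == sg]
        if len(pool) < filters.n_target_per_subgroup:
            logger.warning("subgroup %s: only %d survivors for a target of %d; "
                           "taking all", sg, len(pool), filters.n_target_per_subgroup)
            selected.append(pool)
        else:
            take = rng.choice(len(pool), size=filters.n_target_per_subgroup,
                              replace=False)
            selected.append(pool.iloc[np.sort(take)])
    final = pd.concat(selected) if selected else df.iloc[:0]
    stages["final_draw"] = final["subgroup"].value_counts()

    attrition = pd.DataFrame(stages).fillna(0).astype(int)
    attrition.index.name = "subgroup"
    return final["sample_id"].astype(str).tolist(), attrition.sort_index()


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way ANOVA of ``values`` across ``groups``.

    F = MSB / MSW from the between/within sums-of-squares decomposition;
    the p-value comes from the F(df_between, df_within) distribution.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    chunks = [values[groups == grp] for grp in uniq]
    if min(len(c) for c in chunks) < 2:
        raise ValueError("every group needs at least 2 values")
    grand = values.mean()
    ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in chunks)
    ssw = sum(((c - c.mean()) ** 2).sum() for c in chunks)
    df_b = len(uniq) - 1
    df_w = len(values) - len(uniq)
    if ssw == 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(scipy.stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def sire_count_summary(counts) -> dict:
    """Breed-report convention for per-subgroup sire counts: integer-rounded
    mean and population (divide-by-n) standard deviation."""
    arr = np.asarray(counts, dtype=float)
    return {"mean": int(round(arr.mean())), "sd": int(round(arr.std(ddof=0)))}


def descriptive_report(metadata: pd.DataFrame) -> dict:
    """Herd/sire summary of a selected cohort (breed-report conventions).

    The mean sire count per subgroup is rounded to an integer; its SD uses
    the population (divide-by-n) formula; animals per herd is reported to
    two decimals.
    """
    per_subgroup = metadata.groupby("subgroup")["sire_id"].nunique()
    sire_counts = per_subgroup.to_numpy(dtype=float)
    n_animals = len(metadata)
    n_herds = metadata["herd_id"].nunique()
    n_sires = metadata["sire_id"].nunique()
    sire_subgroups = metadata.groupby("sire_id")["subgroup"].nunique()
    summary = sire_count_summary(sire_counts) if len(sire_counts) else {"mean": 0, "sd": 0}
    return {
        "n_animals": n_animals,
        "n_herds": n_herds,
        "n_sires": n_sires,
        "sires_per_subgroup": per_subgroup.to_dict(),
        "mean_sires_per_subgroup": summary["mean"],
        "sd_sires_per_subgroup": summary["sd"],
        "animals_per_herd": round(n_animals / n_herds, 2) if n_herds else 0.0,
        "cows_per_sire": round(n_animals / n_sires, 2) if n_sires else 0.0,
        "frac_sires_multi_subgroup": float((sire_subgroups > 1).mean()) if n_sires else 0.0,
    }


# ---------------------------------------------------------------------------
# configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class StructureSettings:
    k_max: int = 20
    kmeans_n_starts: int = 10
    scan_n_pcs: int = 100
    npc_grid: tuple[int, ...] = (10, 25, 50, 100)
    xval_reps: int = 30
    xval_training_fraction: float = 0.9
    pairwise_reps: int = 10
    pairwise_training_fraction: float = 0.8
    pairwise_n_pcs: int = 50


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to/from YAML or JSON."""

    out_dir: str = "rohstruct_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: SimParams | None = None
    # ... or read genotypes from disk
    plink_prefix: str | None = None
    plink_format: str = "binary"          # or "text"
    apply_cohort_filters: bool = False
    cohort: CohortFilters = field(default_factory=CohortFilters)
    qc: QCThresholds = field(default_factory=QCThresholds)
    ld: LDPruneParams = field(default_factory=LDPruneParams)
    roh: ROHParams = field(default_factory=ROHParams)
    structure: StructureSettings = field(default_factory=StructureSettings)
    consensus_support_min: float = 0.30

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        caster = {"simulate": SimParams, "cohort": CohortFilters,
                  "qc": QCThresholds, "ld": LDPruneParams, "roh": ROHParams,
                  "structure": StructureSettings}
        for key, typ in caster.items():
            if isinstance(d.get(key), dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in d[key].items()}
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str | None = None
               ) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run cohort selection, QC, the ROH branch and the structure branch.

    ROH detection runs on the full post-QC panel; LD pruning is applied only
    for the structure branch.  Returns a dict of the in-memory results; all
    tables are also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    # -- input stage
    if config.simulate is not None:
        dataset, truth = simulate_herd_cohort(config.simulate)
        results["sim_truth"] = truth
    elif config.plink_prefix is not None:
        if config.plink_format == "binary":
            dataset = read_plink_binary(config.plink_prefix)
        else:
            dataset = read_plink_text(config.plink_prefix + ".ped",
                                      config.plink_prefix + ".map")
    else:
        raise ValueError("config must set either 'simulate' or 'plink_prefix'")

    # -- cohort stage
    if config.apply_cohort_filters:
        ids, attrition = select_cohort(dataset.samples, config.cohort)
        dataset = dataset.subset_by_sample_id(ids)
        attrition.to_csv(out / "cohort_attrition.tsv", sep="\t")
        results["attrition"] = attrition
    results["descriptives"] = descriptive_report(dataset.samples)
    (out / "cohort_descriptives.json").write_text(
        json.dumps(results["descriptives"], indent=2, sort_keys=True))

    # -- QC stage
    dataset, qc_report = apply_qc(dataset, config.qc)
    results["qc_report"] = qc_report
    _write_tsv(qc_report.to_frame(), out / "qc_report.tsv")

    # -- ROH branch (unpruned post-QC panel)
    segments = detect_roh(dataset, config.roh)
    seg_df = segments_to_frame(segments)
    _write_tsv(seg_df, out / "roh_segments.tsv",
               "1-based closed intervals; length_bp = end_bp - start_bp")
    froh_df = froh_table(segments, dataset)
    _write_tsv(froh_df, out / "froh.tsv")
    subgroup_by_id = dataset.samples.set_index("sample_id")["subgroup"]
    summary = roh_summary(segments, subgroup_by_id)
    _write_tsv(summary, out / "roh_class_summary.tsv")
    regions = consensus_regions(segments, subgroup_by_id, dataset.variants,
                                config.consensus_support_min)
    _write_tsv(consensus_to_frame(regions), out / "consensus_regions.tsv",
               "columns mirror: Subgroup, Chromosome, From (Bp), To (Bp), Length (Mb)")
    results.update(segments=segments, froh=froh_df, roh_summary=summary,
                   consensus=regions)

    labels = dataset.samples["subgroup"].astype(str).to_numpy()
    froh_values = froh_df["froh_genome"].to_numpy()
    if len(np.unique(labels)) >= 2:
        try:
            anova = anova_oneway(froh_values, labels)
        except ValueError as err:  # e.g. no ROH anywhere: F undefined
            logger.warning("skipping F_ROH ANOVA: %s", err)
            anova = None
        if anova is not None:
            results["anova_froh"] = anova
            (out / "anova_froh.json").write_text(
                json.dumps(asdict(anova), indent=2))
        chrom_rows = []
        for col in froh_df.columns:
            if not col.startswith("froh_chr"):
                continue
            vals = froh_df[col].to_numpy()
            try:
                res = anova_oneway(vals, labels)
            except ValueError:
                continue
            chrom_rows.append({"chrom": int(col.removeprefix("froh_chr")),
                               "f_stat": res.f_stat, "p_value": res.p_value})
        if chrom_rows:
            _write_tsv(pd.DataFrame(chrom_rows).sort_values("chrom"),
                       out / "anova_froh_by_chrom.tsv")

    # -- structure branch (LD-pruned panel)
    retained = ld_prune(dataset, config.ld, seed=int(rng.integers(2 ** 31)))
    (out / "pruned_snps.txt").write_text("\n".join(retained) + "\n")
    pruned = dataset.subset_by_variant_id(retained)
    results["n_snps_roh_branch"] = dataset.n_variants
    results["n_snps_structure_branch"] = pruned.n_variants

    st = config.structure
    n_pcs_avail = min(pruned.n_samples - 1, pruned.n_variants)
    basis, scores = pca_genotypes(pruned, n_components=n_pcs_avail)
    scan = kmeans_bic_scan(scores[:, :min(st.scan_n_pcs, n_pcs_avail)],
                           k_max=min(st.k_max, pruned.n_samples - 1),
                           n_starts=st.kmeans_n_starts,
                           seed=int(rng.integers(2 ** 31)))
    _write_tsv(pd.DataFrame({"k": scan.k_values, "wss": scan.wss,
                             "bic": scan.bic}),
               out / "bic_scan.tsv", f"k_best = {scan.k_best}")
    results["bic_scan"] = scan

    n_pcs_fit = min(st.pairwise_n_pcs, n_pcs_avail)
    model = dapc_fit(scores, labels, n_pcs=n_pcs_fit, basis=basis)
    assign = reassignment_accuracy(dapc_predict(model, scores, kind="scores"),
                                   labels)
    post = pd.DataFrame(assign.posterior, columns=model.group_labels)
    post.insert(0, "sample_id", dataset.samples["sample_id"].to_numpy())
    post["assigned"] = assign.assigned
    _write_tsv(post, out / "dapc_posteriors.tsv")
    (out / "assignment_accuracy.json").write_text(json.dumps({
        "overall": assign.accuracy_overall,
        "by_group": assign.accuracy_by_group}, indent=2, sort_keys=True))
    results["assignment"] = assign

    if len(np.unique(labels)) >= 2:
        pw = pairwise_validation_matrix(
            pruned, labels, n_pcs=n_pcs_fit,
            training_fraction=st.pairwise_training_fraction,
            reps=st.pairwise_reps, seed=int(rng.integers(2 ** 31)))
        _write_tsv(pw, out / "pairwise_validation.tsv")
        results["pairwise"] = pw

    (out / "run_log.json").write_text(json.dumps({
        "rohstruct_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "n_samples": dataset.n_samples,
        "n_snps_roh_branch": results["n_snps_roh_branch"],
        "n_snps_structure_branch": results["n_snps_structure_branch"],
    }, indent=2, sort_keys=True))
    return results
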