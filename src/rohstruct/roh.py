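"""Runs of homozygosity: sliding-window detection, genomic inbreeding
(F_ROH), length-class summaries and consensus shared-homozygosity regions.

Detection follows the sliding-window approach standard for SNP-chip cattle
data: a 40-SNP window slides one SNP at a time along each autosome; a window
is "homozygous" when it contains at most one heterozygote and at most one
missing call; a SNP is in a homozygous state when at least 5 % of the
windows overlapping it are homozygous.  Maximal homozygous stretches are
split at inter-SNP gaps above 500 kb and kept as ROH when they span at
least 40 SNPs and 1 Mb with at least one SNP per 50 kb.

Coordinates are 1-based; a segment's length is ``end_bp - start_bp``, the
span between its first and last SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plink import MISSING, GenotypeDataset

#: ROH length classes in Mb, left-closed right-open ([16, inf) for the last).
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb")


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH detection parameters (cattle SNP-chip defaults)."""

    window_snps: int = 40
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    window_hom_prop_min: float = 0.05
    min_snps_per_roh: int = 40
    min_length_bp: int = 1_000_000
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 500_000


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity in one individual."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class FrohResult:
    sample_id: str
    froh_genome: float
    froh_by_chrom: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConsensusRegion:
    """Interval homozygous in more than ``support`` of a subgroup."""

    subgroup_set: tuple[str, ...]
    chrom: int
    start_bp: int
    end_bp: int
    support: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# window states
# ---------------------------------------------------------------------------

def window_homozygosity_states(genos: np.ndarray,
                               params: ROHParams = ROHParams()) -> np.ndarray:
    """Per-SNP homozygous state for one chromosome of one individual.

    Every contiguous window of ``window_snps`` SNPs is homozygous iff it has
    at most ``max_het_per_window`` heterozygotes and ``max_missing_per_window``
    missing calls.  A SNP's state is True iff the fraction of existing
    overlapping windows that are homozygous is >= ``window_hom_prop_min``.
    A chromosome shorter than the window is scanned as a single truncated
    window covering all its SNPs.
    """
    genos = np.asarray(genos)
    m = len(genos)
    if m == 0:
        return np.zeros(0, dtype=bool)
    w = min(params.window_snps, m)
    het = (genos == 1).astype(np.int32)
    mis = (genos == MISSING).astype(np.int32)
    kernel_het = np.convolve(het, np.ones(w, dtype=np.int32), mode="valid")
    kernel_mis = np.convolve(mis, np.ones(w, dtype=np.int32), mode="valid")
    win_ok = ((kernel_het <= params.max_het_per_window)
              & (kernel_mis <= params.max_missing_per_window))
    n_win = len(win_ok)  # = m - w + 1
    # SNP j overlaps windows [max(0, j-w+1), min(j, n_win-1)]
    csum = np.concatenate([[0], np.cumsum(win_ok)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_overlap = hi - lo + 1
    n_hom = csum[hi + 1] - csum[lo]
    return n_hom / n_overlap >= params.window_hom_prop_min


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _emit_runs(pos: np.ndarray, states: np.ndarray, chrom: int, sample_id: str,
               params: ROHParams) -> list[ROHSegment]:
    """Turn per-SNP states into qualifying segments for one chromosome."""
    segments: list[ROHSegment] = []
    if not states.any():
        return segments
    padded = np.concatenate([[False], states, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for a, b in zip(edges[::2], edges[1::2]):  # run = indices [a, b)
        # split at inter-SNP gaps above max_gap_bp
        run_pos = pos[a:b]
        gaps = np.flatnonzero(np.diff(run_pos) > params.max_gap_bp)
        bounds = np.concatenate([[0], gaps + 1, [b - a]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            n_snps = int(e - s)
            start, end = int(run_pos[s]), int(run_pos[e - 1])
            length = end - start
            if (n_snps >= params.min_snps_per_roh
                    and length >= params.min_length_bp
                    and length / n_snps <= params.min_density_bp_per_snp):
                segments.append(ROHSegment(sample_id, int(chrom), start, end, n_snps))
    return segments


def detect_roh_sample(genos_row: np.ndarray, variants: pd.DataFrame,
                      sample_id: str,
                      params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH for one individual over all autosomes."""
    segments: list[ROHSegment] = []
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        states = window_homozygosity_states(genos_row[sel], params)
        segments.extend(_emit_runs(pos[sel], states, chrom, sample_id, params))
    return segments


def detect_roh(dataset: GenotypeDataset,
               params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH for every sample in the dataset (position-sorted output)."""
    segments: list[ROHSegment] = []
    ids = dataset.samples["sample_id"].tolist()
    for i, sid in enumerate(ids):
        segments.extend(detect_roh_sample(dataset.calls[i], dataset.variants,
                                          str(sid), params))
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp)
         for s in segments],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


# ---------------------------------------------------------------------------
# genomic inbreeding
# ---------------------------------------------------------------------------

def map_chromosome_spans(variants: pd.DataFrame) -> dict[int, int]:
    """Per-chromosome map-covered length: last SNP position - first."""
    spans = {}
    for chrom, grp in variants.groupby("chrom"):
        pos = grp["pos_bp"].to_numpy()
        spans[int(chrom)] = int(pos.max() - pos.min())
    return spans


def froh(segments: list[ROHSegment], variants: pd.DataFrame,
         sample_id: str) -> FrohResult:
    """Genomic inbreeding for one individual.

    F_ROH = total ROH length / total map-covered autosome length, where the
    denominator is the sum over chromosomes of (last SNP - first SNP).  The
    per-chromosome coefficients use the same convention.
    """
    spans = map_chromosome_spans(variants)
    l_total = sum(spans.values())
    by_chrom: dict[int, float] = {}
    total = 0
    for seg in segments:
        if seg.sample_id != sample_id:
            continue
        if seg.chrom not in spans:
            raise ValueError(f"segment on chromosome {seg.chrom} absent from map")
        total += seg.length_bp
        by_chrom[seg.chrom] = by_chrom.get(seg.chrom, 0) + seg.length_bp
    froh_by_chrom = {c: (by_chrom.get(c, 0) / spans[c] if spans[c] else 0.0)
                     for c in spans}
    return FrohResult(sample_id, total / l_total if l_total else 0.0, froh_by_chrom)


def froh_table(segments: list[ROHSegment], dataset: GenotypeDataset) -> pd.DataFrame:
    """F_ROH per sample (genome-wide and per chromosome) as a tidy table."""
    spans = map_chromosome_spans(dataset.variants)
    l_total = sum(spans.values())
    seg_df = segments_to_frame(segments)
    rows = []
    for sid in dataset.samples["sample_id"].astype(str):
        sub = seg_df[seg_df["sample_id"] == sid]
        total = int(sub["length_bp"].sum())
        row = {"sample_id": sid, "froh_genome": total / l_total if l_total else 0.0}
        per_chrom = sub.groupby("chrom")["length_bp"].sum().to_dict()
        for c, span in spans.items():
            row[f"froh_chr{c}"] = (per_chrom.get(c, 0) / span) if span else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# length classes and summaries
# ---------------------------------------------------------------------------

def classify_roh_lengths(segments: list[ROHSegment]) -> dict[str, int]:
    """Count segments per length class (left-closed right-open bins)."""
    counts = dict.fromkeys(LENGTH_CLASS_LABELS, 0)
    edges_bp = [e * 1e6 for e in LENGTH_CLASS_EDGES_MB]
    for seg in segments:
        if seg.length_bp < edges_bp[0]:
            raise ValueError(
                f"segment length {seg.length_bp} bp below the 1 Mb detector floor")
        k = int(np.searchsorted(edges_bp, seg.length_bp, side="right")) - 1
        counts[LENGTH_CLASS_LABELS[k]] += 1
    return counts


def roh_summary(segments: list[ROHSegment],
                sample_subgroups: pd.Series) -> pd.DataFrame:
    """Mean ROH count per individual, per subgroup and length class.

    ``sample_subgroups`` maps sample_id -> subgroup for the whole cohort;
    individuals without any ROH still count in the denominator.
    """
    group_sizes = sample_subgroups.value_counts()
    seg_df = segments_to_frame(segments)
    seg_df["subgroup"] = seg_df["sample_id"].map(sample_subgroups)
    rows = []
    for subgroup, n_ind in group_sizes.items():
        sub = seg_df[seg_df["subgroup"] == subgroup]
        counts = classify_roh_lengths(
            [s for s in segments
             if sample_subgroups.get(s.sample_id) == subgroup])
        row = {"subgroup": subgroup, "n_individuals": int(n_ind),
               "mean_n_roh": len(sub) / n_ind}
        for label in LENGTH_CLASS_LABELS:
            row[f"mean_n_roh_{label}"] = counts[label] / n_ind
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# consensus regions
# ---------------------------------------------------------------------------

def _subgroup_consensus(segments: list[ROHSegment], sample_ids: list[str],
                        variants: pd.DataFrame,
                        support_min: float) -> list[tuple[int, int, int, float]]:
    """Maximal intervals covered by ROH in > support_min of ``sample_ids``.

    Coverage is evaluated on the intervals between consecutive SNP positions;
    emitted regions snap to SNP positions.  Returns (chrom, start, end,
    max support) tuples.
    """
    n_ind = len(sample_ids)
    if n_ind == 0:
        return []
    id_set = set(sample_ids)
    out = []
    for chrom, grp in variants.groupby("chrom"):
        pos = np.unique(grp["pos_bp"].to_numpy())
        if len(pos) < 2:
            continue
        n_gaps = len(pos) - 1
        # count, per inter-SNP interval k = (pos[k], pos[k+1]), individuals
        # whose ROH spans it; one diff array per individual is unnecessary —
        # segments of one individual are disjoint, so a single diff suffices
        cover = np.zeros(n_gaps + 1, dtype=np.int32)
        for seg in segments:
            if seg.chrom != chrom or seg.sample_id not in id_set:
                continue
            i = int(np.searchsorted(pos, seg.start_bp, side="left"))
            j = int(np.searchsorted(pos, seg.end_bp, side="right")) - 1
            if j > i:
                cover[i] += 1
                cover[j] -= 1
        frac = np.cumsum(cover)[:n_gaps] / n_ind
        hot = frac > support_min
        if not hot.any():
            continue
        padded = np.concatenate([[False], hot, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            out.append((int(chrom), int(pos[a]), int(pos[b]),
                        float(frac[a:b].max())))
    return out


def consensus_regions(segments: list[ROHSegment],
                      sample_subgroups: pd.Series,
                      variants: pd.DataFrame,
                      support_min: float = 0.30) -> list[ConsensusRegion]:
    """Regions homozygous in more than ``support_min`` of a subgroup.

    Evaluated independently per subgroup; regions with identical coordinates
    across subgroups are merged into one record listing every supporting
    subgroup.  The threshold is strict (support must exceed ``support_min``).
    """
    by_coords: dict[tuple[int, int, int], tuple[list[str], float]] = {}
    for subgroup in sorted(sample_subgroups.dropna().unique()):
        ids = sample_subgroups[sample_subgroups == subgroup].index.astype(str).tolist()
        for chrom, start, end, support in _subgroup_consensus(
                segments, ids, variants, support_min):
            key = (chrom, start, end)
            groups, best = by_coords.get(key, ([], 0.0))
            groups.append(str(subgroup))
            by_coords[key] = (groups, max(best, support))
    regions = [ConsensusRegion(tuple(groups), chrom, start, end, support)
               for (chrom, start, end), (groups, support)
               in sorted(by_coords.items())]
    return regions


def consensus_to_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(",".join(r.subgroup_set), r.chrom, r.start_bp, r.end_bp,
          round(r.length_bp / 1e6, 2), round(r.support, 4))
         for r in regions],
        columns=["subgroups", "chrom", "from_bp", "to_bp", "length_mb", "support"],
    )
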