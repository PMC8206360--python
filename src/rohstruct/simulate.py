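"""Synthetic herd genotypes with known ground truth.

The generator emulates the statistical structure the analysis assumes in a
commercial dairy cattle cohort: several production subgroups of one breed
with subtle allele-frequency divergence, SNP-chip genotypes on the 29
autosomes, autozygous tracts producing realistic runs of homozygosity, and
genotyping noise.  Divergence follows the Balding-Nichols model: subgroup
allele frequencies are Beta-distributed around an ancestral frequency with
dispersion set by F_ST; genotypes are then binomial draws, independent
across SNPs (no within-subgroup LD is simulated).

Defaults mirror the cohort design the pipeline targets — five subgroups
(AS, DM, GP, PR, TR) of 200 cows on 29 autosomes totalling ~2.5 Gb — with
the SNP count scaled to 15,000 so test runs stay fast; full chip densities
are supported by raising ``n_snps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plink import MISSING, AUTOSOMES, GenotypeDataset

#: Approximate physical lengths of the 29 cattle autosomes (bp), ~2.5 Gb total.
CATTLE_CHROM_LENGTHS_BP: tuple[int, ...] = tuple(int(mb * 1e6) for mb in (
    158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
    106.9, 87.2, 83.5, 82.4, 85.0, 81.0, 75.2, 66.0, 64.1, 72.0,
    71.6, 61.4, 52.5, 62.7, 42.4, 51.7, 45.6, 45.9, 51.1,
))

DEFAULT_SUBGROUPS = ("AS", "DM", "GP", "PR", "TR")


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation settings."""

    n_pops: int = 5
    n_per_pop: int = 200
    n_snps: int = 15_000
    fst: float = 0.03
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    chrom_lengths_bp: tuple[int, ...] = CATTLE_CHROM_LENGTHS_BP
    spacing: str = "uniform"          # or "poisson"
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fst <= 0.5):
            raise ValueError("fst must be in [0, 0.5]")
        for rate in (self.missing_rate, self.genotype_error_rate):
            if not (0.0 <= rate <= 0.2):
                raise ValueError("rates must be in [0, 0.2]")
        if len(self.chrom_lengths_bp) != len(AUTOSOMES):
            raise ValueError("need one length per autosome")
        if self.spacing not in ("uniform", "poisson"):
            raise ValueError("spacing must be 'uniform' or 'poisson'")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    true_pop: list[str]
    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray                 # n_pops x n_snps
    injected_tracts: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    true_autozygous_fraction: dict[str, float] = field(default_factory=dict)


def _pop_labels(n_pops: int) -> list[str]:
    if n_pops <= len(DEFAULT_SUBGROUPS):
        return list(DEFAULT_SUBGROUPS[:n_pops])
    return [f"P{i + 1}" for i in range(n_pops)]


def make_variant_map(params: SimParams, rng: np.random.Generator | None = None
                     ) -> pd.DataFrame:
    """Physical SNP map: counts proportional to chromosome length.

    Positions are 1-based and strictly increasing per chromosome; spacing is
    either even ("uniform") or a sorted Poisson process ("poisson", with
    +1 bp jitter applied to any duplicate draw).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    lengths = np.asarray(params.chrom_lengths_bp, dtype=float)
    # largest-remainder allocation so counts sum exactly to n_snps
    raw = params.n_snps * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    remainder = params.n_snps - counts.sum()
    counts[np.argsort(raw - np.floor(raw))[::-1][:remainder]] += 1
    rows = []
    for chrom, (n_c, length) in enumerate(zip(counts, lengths), start=1):
        if n_c == 0:
            continue
        if params.spacing == "uniform":
            # n SNPs at k*L/(n+1): even interior spacing, ends uncovered
            pos = (np.arange(1, n_c + 1, dtype=np.int64)
                   * np.int64(length)) // (n_c + 1)
            pos = np.maximum(pos, 1)
        else:
            pos = np.sort(rng.integers(1, int(length) + 1, size=n_c))
        # enforce strict increase (+1 bp jitter on collisions)
        pos = np.maximum.accumulate(pos + np.arange(n_c) * 0) if n_c else pos
        for k in range(1, n_c):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        rows.append(pd.DataFrame({
            "variant_id": [f"snp_{chrom}_{k + 1}" for k in range(n_c)],
            "chrom": chrom,
            "pos_bp": pos.astype(np.int64),
            "allele_a": "A",
            "allele_b": "B",
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_subpopulations(params: SimParams) -> tuple[GenotypeDataset, SimTruth]:
    """Balding-Nichols genotypes for ``n_pops`` subgroups.

    Ancestral frequencies are Uniform over ``ancestral_maf_range``; each
    subgroup's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``
    (F = 0 degenerates to the ancestral frequency); genotypes are
    Binomial(2, p_pop) per SNP.  ``missing_rate`` / ``genotype_error_rate``
    are applied last via :func:`perturb`.
    """
    rng = np.random.default_rng(params.seed)
    variants = make_variant_map(params, rng)
    n_snps = len(variants)
    p_anc = rng.uniform(*params.ancestral_maf_range, size=n_snps)
    if params.fst > 0:
        f = params.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pop_freqs = rng.beta(a, b, size=(params.n_pops, n_snps))
    else:
        pop_freqs = np.tile(p_anc, (params.n_pops, 1))
    labels = _pop_labels(params.n_pops)
    calls = np.empty((params.n_pops * params.n_per_pop, n_snps), dtype=np.int8)
    true_pop = []
    for k in range(params.n_pops):
        rows = slice(k * params.n_per_pop, (k + 1) * params.n_per_pop)
        calls[rows] = rng.binomial(2, pop_freqs[k],
                                   size=(params.n_per_pop, n_snps)).astype(np.int8)
        true_pop.extend([labels[k]] * params.n_per_pop)
    sample_ids = [f"{pop}_{i % params.n_per_pop + 1:04d}"
                  for i, pop in enumerate(true_pop)]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "subgroup": true_pop,
        "herd_id": pd.NA,
        "sire_id": pd.NA,
        "birth_year": pd.array([pd.NA] * len(sample_ids), dtype="Int64"),
        "panel_density": pd.array([pd.NA] * len(sample_ids), dtype="Int64"),
    })
    dataset = GenotypeDataset(samples, variants, calls)
    truth = SimTruth(true_pop=true_pop, ancestral_freqs=p_anc, pop_freqs=pop_freqs)
    if params.missing_rate > 0 or params.genotype_error_rate > 0:
        dataset = perturb(dataset, params.missing_rate,
                          params.genotype_error_rate,
                          seed=int(rng.integers(2 ** 31)))
    return dataset, truth


def inject_autozygosity(dataset: GenotypeDataset, sample_id: str,
                        target_fraction: float, mean_tract_mb: float,
                        seed: int, pop_freqs: np.ndarray | None = None
                        ) -> tuple[GenotypeDataset, list[tuple[int, int, int]]]:
    """Overwrite one sample with homozygous tracts covering a target fraction.

    Non-overlapping tracts with exponential lengths (mean ``mean_tract_mb``)
    are placed uniformly on the map-covered spans until their total length
    reaches ``target_fraction`` of the total span.  Inside a tract every SNP
    becomes homozygous for a single allele drawn from ``pop_freqs`` (the
    sample's subgroup frequency; falls back to the cohort frequency).
    Returns the modified dataset and the placed (chrom, start, end) tracts.
    """
    if not (0.0 <= target_fraction <= 0.5):
        raise ValueError("target_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    i = int(dataset.samples.index[dataset.samples["sample_id"] == sample_id][0])
    variants = dataset.variants
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    spans = {}
    for c in np.unique(chroms):
        p = pos[chroms == c]
        spans[int(c)] = (int(p.min()), int(p.max()))
    span_lengths = {c: b - a for c, (a, b) in spans.items()}
    l_total = sum(span_lengths.values())
    chrom_ids = np.array(sorted(spans))
    chrom_w = np.array([span_lengths[c] for c in chrom_ids], dtype=float)
    chrom_w /= chrom_w.sum()

    if pop_freqs is None:
        obs = dataset.calls != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            pop_freqs = (np.where(obs, dataset.calls, 0).sum(axis=0)
                         / np.maximum(2.0 * obs.sum(axis=0), 1.0))

    placed: dict[int, list[tuple[int, int]]] = {int(c): [] for c in chrom_ids}
    total = 0
    attempts = 0
    while total < target_fraction * l_total and target_fraction > 0:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                "could not place non-overlapping tracts after 1000 attempts; "
                "reduce target_fraction or mean_tract_mb")
        c = int(rng.choice(chrom_ids, p=chrom_w))
        lo, hi = spans[c]
        length = int(rng.exponential(mean_tract_mb * 1e6))
        length = max(length, 1)
        if length >= hi - lo:
            continue
        start = int(rng.integers(lo, hi - length))
        end = start + length
        if any(not (end < a or start > b) for a, b in placed[c]):
            continue
        placed[c].append((start, end))
        total += length
        attempts = 0  # the limit counts consecutive failures

    calls = dataset.calls.copy()
    tracts = []
    for c in sorted(placed):
        for start, end in sorted(placed[c]):
            sel = np.flatnonzero((chroms == c) & (pos >= start) & (pos <= end))
            hom_b = rng.random(len(sel)) < pop_freqs[sel]
            calls[i, sel] = np.where(hom_b, 2, 0).astype(np.int8)
            tracts.append((c, start, end))
    out = GenotypeDataset(dataset.samples, dataset.variants, calls)
    return out, tracts


def tract_fraction(tracts: list[tuple[int, int, int]],
                   variants: pd.DataFrame) -> float:
    """Fraction of the map-covered genome occupied by the given tracts."""
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    l_total = 0
    for c in np.unique(chroms):
        p = pos[chroms == c]
        l_total += int(p.max() - p.min())
    covered = sum(end - start for _, start, end in tracts)
    return covered / l_total if l_total else 0.0


def perturb(dataset: GenotypeDataset, missing_rate: float,
            genotype_error_rate: float, seed: int) -> GenotypeDataset:
    """Apply genotyping noise: random missingness, then hom->het flips.

    Each call independently becomes missing with probability
    ``missing_rate``; surviving homozygous calls flip to heterozygous with
    probability ``genotype_error_rate`` (the error mode that interrupts
    runs of homozygosity).
    """
    rng = np.random.default_rng(seed)
    calls = dataset.calls.copy()
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if genotype_error_rate > 0:
        hom = (calls == 0) | (calls == 2)
        flip = hom & (rng.random(calls.shape) < genotype_error_rate)
        calls[flip] = 1
    return GenotypeDataset(dataset.samples, dataset.variants, calls)


# ---------------------------------------------------------------------------
# full cohort with breeding metadata
# ---------------------------------------------------------------------------

def make_cohort_metadata(n_candidates_per_subgroup: int = 400,
                         subgroups: tuple[str, ...] = DEFAULT_SUBGROUPS,
                         seed: int = 0) -> pd.DataFrame:
    """Candidate-animal metadata table, including filter-ineligible records.

    Emulates a breed-association extract: most candidates are cows born
    2014-2018 genotyped on >= 50 K chips in herds of plausible sizes, but a
    fraction carry an older birth year, a low-density panel, or sit in a
    sparsely genotyped herd, so cohort-selection filters have work to do.
    """
    rng = np.random.default_rng(seed)
    panel_choices = np.array([7_931, 54_609, 76_883, 138_892])
    rows = []
    for sg in subgroups:
        n_herds = max(6, n_candidates_per_subgroup // 18)
        herd_ids = [f"{sg}_H{h + 1:03d}" for h in range(n_herds)]
        herd_w = rng.dirichlet(np.full(n_herds, 2.0))
        n_sires = max(10, n_candidates_per_subgroup // 4)
        sire_ids = [f"S{rng.integers(1, 3000):05d}" for _ in range(n_sires)]
        for k in range(n_candidates_per_subgroup):
            rows.append({
                "sample_id": f"{sg}_{k + 1:05d}",
                "subgroup": sg,
                "herd_id": herd_ids[int(rng.choice(n_herds, p=herd_w))],
                "sire_id": sire_ids[int(rng.integers(n_sires))],
                "birth_year": int(rng.choice(
                    [2012, 2013, 2014, 2015, 2016, 2017, 2018, 2019],
                    p=[0.04, 0.06, 0.17, 0.17, 0.18, 0.17, 0.16, 0.05])),
                "panel_density": int(rng.choice(
                    panel_choices, p=[0.08, 0.52, 0.25, 0.15])),
            })
    return pd.DataFrame(rows)


def simulate_herd_cohort(params: SimParams = SimParams(),
                         mean_froh: float = 0.065, froh_sd: float = 0.015,
                         mean_tract_mb: float = 2.11
                         ) -> tuple[GenotypeDataset, SimTruth]:
    """Balding-Nichols cohort with injected autozygosity and herd metadata.

    Every cow receives autozygous tracts targeting a Normal(``mean_froh``,
    ``froh_sd``) genome fraction (clipped at 0), with tract lengths
    exponential around ``mean_tract_mb`` — yielding genomic inbreeding and
    mostly short runs in the range typical of intensively selected dairy
    cattle.
    """
    dataset, truth = simulate_subpopulations(params)
    rng = np.random.default_rng(params.seed + 1)
    meta = make_cohort_metadata(
        n_candidates_per_subgroup=params.n_per_pop,
        subgroups=tuple(_pop_labels(params.n_pops)),
        seed=int(rng.integers(2 ** 31)))
    # candidate table rows map 1:1 onto simulated samples, in order
    samples = dataset.samples.copy()
    for col in ("herd_id", "sire_id", "birth_year", "panel_density"):
        samples[col] = meta[col].to_numpy()
    dataset = GenotypeDataset(samples, dataset.variants, dataset.calls)

    labels = _pop_labels(params.n_pops)
    calls = dataset.calls
    for i, sid in enumerate(dataset.samples["sample_id"].astype(str)):
        target = float(np.clip(rng.normal(mean_froh, froh_sd), 0.0, 0.4))
        pop_idx = labels.index(truth.true_pop[i])
        dataset_i, tracts = inject_autozygosity(
            GenotypeDataset(dataset.samples, dataset.variants, calls),
            sid, target, mean_tract_mb, seed=int(rng.integers(2 ** 31)),
            pop_freqs=truth.pop_freqs[pop_idx])
        calls = dataset_i.calls
        truth.injected_tracts[sid] = tracts
        truth.true_autozygous_fraction[sid] = tract_fraction(
            tracts, dataset.variants)
    dataset = GenotypeDataset(dataset.samples, dataset.variants, calls)
    if params.missing_rate > 0 or params.genotype_error_rate > 0:
        dataset = perturb(dataset, params.missing_rate,
                          params.genotype_error_rate,
                          seed=int(rng.integers(2 ** 31)))
    return dataset, truth
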