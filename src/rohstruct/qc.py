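"""Genotype quality control: allele-frequency, missingness and HWE filters,
plus windowed LD (r^2) pruning.

Filter defaults follow common SNP-chip practice for cattle panels: variants
are dropped when MAF < 0.01, per-SNP missingness > 0.10 or the exact
Hardy-Weinberg test gives P < 1e-4; samples are dropped first when their
missing fraction exceeds 0.10.  LD pruning slides a 50-SNP window in steps
of 5 SNPs and removes one member of every retained pair with r^2 > 0.6.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .plink import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.10
    ind_missing_max: float = 0.10
    hwe_p_min: float = 1e-4


@dataclass(frozen=True)
class LDPruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.6

    def __post_init__(self):
        if not (self.window_snps > self.step_snps >= 1):
            raise ValueError("require window_snps > step_snps >= 1")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must be in (0, 1]")


@dataclass
class QCReport:
    n_samples_in: int
    n_variants_in: int
    n_removed_ind: int
    n_removed_geno: int
    n_removed_maf: int
    n_removed_hwe: int
    n_samples_retained: int
    n_variants_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def allele_b_frequency(calls: np.ndarray) -> np.ndarray:
    """Frequency of allele_b per variant; NaN where all calls are missing.

    ``calls`` may be a single column (1-D) or a samples x variants matrix.
    """
    calls = np.asarray(calls)
    one_dim = calls.ndim == 1
    if one_dim:
        calls = calls[:, None]
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    dosage_sum = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, dosage_sum / (2.0 * n_obs), np.nan)
    return float(p[0]) if one_dim else p


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """min(p, 1-p) of the allele_b frequency; NaN where all calls missing."""
    p = allele_b_frequency(calls)
    return np.minimum(p, 1.0 - p) if isinstance(p, np.ndarray) else min(p, 1.0 - p)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

#: Relative tolerance used when comparing configuration probabilities for the
#: two-sided tail; treats floating-point ties as ties.
_HWE_TIE_RTOL = 1e-12


@functools.lru_cache(maxsize=100_000)
def _het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given fixed allele counts.

    Conditional on ``n`` diploid genotypes carrying ``n_minor`` copies of the
    minor allele, returns (het_counts, probabilities) over all reachable
    heterozygote counts (same parity as ``n_minor``).  Probabilities are built
    with a vectorised ratio recurrence and normalised to sum to 1.
    """
    n_major = 2 * n - n_minor
    h_max = min(n_minor, n_major)
    h0 = n_minor % 2
    hets = np.arange(h0, h_max + 1, 2)
    if len(hets) == 1:
        return hets, np.ones(1)
    # P(h+2)/P(h) = 4 * nAA(h) * nBB(h) / ((h+2)(h+1))
    h = hets[:-1].astype(float)
    n_aa = (n_major - h) / 2.0
    n_bb = (n_minor - h) / 2.0
    ratios = 4.0 * n_aa * n_bb / ((h + 2.0) * (h + 1.0))
    probs = np.empty(len(hets))
    probs[0] = 1.0
    np.cumprod(ratios, out=probs[1:])
    m = probs.max()
    probs /= m
    probs /= probs.sum()
    return hets, probs


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one SNP.

    Probability-ordered tail: conditional on the observed allele counts, sum
    the probabilities of every reachable heterozygote count whose exact
    probability does not exceed that of the observed count.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_b = n_ab + 2 * n_bb
    n_minor = min(n_b, 2 * n - n_b)
    hets, probs = _het_distribution(n, n_minor)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + _HWE_TIE_RTOL)].sum()))


def hwe_pvalues(calls: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per variant column of a call matrix (NaN if empty)."""
    calls = np.asarray(calls)
    out = np.empty(calls.shape[1])
    for j in range(calls.shape[1]):
        col = calls[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        out[j] = np.nan if n0 + n1 + n2 == 0 else hwe_exact_pvalue(n0, n1, n2)
    return out


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------

def apply_qc(dataset: GenotypeDataset,
             thresholds: QCThresholds = QCThresholds()) -> tuple[GenotypeDataset, QCReport]:
    """Apply sample-missingness, then per-variant GENO / MAF / HWE filters.

    Samples are filtered first so the variant statistics are computed on the
    retained cohort.  A variant failing several criteria is attributed to the
    first failed test in the order GENO, MAF, HWE.
    """
    n_samples_in, n_variants_in = dataset.n_samples, dataset.n_variants
    miss = dataset.calls == MISSING

    ind_miss_frac = miss.mean(axis=1) if n_variants_in else np.zeros(n_samples_in)
    keep_samples = ind_miss_frac <= thresholds.ind_missing_max
    n_removed_ind = int((~keep_samples).sum())
    ds = dataset.take_samples(np.flatnonzero(keep_samples))

    if ds.n_samples == 0:
        logger.warning("QC removed every sample")
        empty = ds.take_variants(np.zeros(0, dtype=int))
        # with no samples left every variant is vacuously all-missing
        return empty, QCReport(n_samples_in, n_variants_in, n_removed_ind,
                               n_variants_in, 0, 0, 0, 0)

    miss_frac = (ds.calls == MISSING).mean(axis=0)
    fail_geno = miss_frac > thresholds.snp_missing_max
    maf = minor_allele_frequency(ds.calls)
    with np.errstate(invalid="ignore"):
        fail_maf = ~fail_geno & (np.isnan(maf) | (maf < thresholds.maf_min))
    undecided = ~fail_geno & ~fail_maf
    fail_hwe = np.zeros(ds.n_variants, dtype=bool)
    pvals = np.ones(ds.n_variants)
    for j in np.flatnonzero(undecided):
        col = ds.calls[:, j]
        pvals[j] = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                                    int((col == 2).sum()))
    fail_hwe = undecided & (pvals < thresholds.hwe_p_min)

    keep = ~(fail_geno | fail_maf | fail_hwe)
    out = ds.take_variants(np.flatnonzero(keep))
    if out.n_variants == 0:
        logger.warning("QC removed every variant")
    report = QCReport(
        n_samples_in=n_samples_in,
        n_variants_in=n_variants_in,
        n_removed_ind=n_removed_ind,
        n_removed_geno=int(fail_geno.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_samples_retained=out.n_samples,
        n_variants_retained=out.n_variants,
    )
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete entries; returns NaN when fewer than two
    complete pairs exist or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for the columns of ``calls``.

    Undefined entries (monomorphic on the complete pairs, or < 2 pairs) are
    set to 0: a variant with no variation carries no LD signal.
    """
    X = calls.astype(float)
    M = (calls != MISSING).astype(float)
    X = X * M
    n = M.T @ M
    sx = X.T @ M
    sy = sx.T
    sxy = X.T @ X
    sxx = (X * X).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(dataset: GenotypeDataset,
             params: LDPruneParams = LDPruneParams(),
             seed: int = 0) -> list[str]:
    """Windowed pairwise LD pruning; returns the retained variant_id list.

    Per chromosome, a window of ``window_snps`` SNPs advances by
    ``step_snps``.  Within each window, while any retained pair exceeds
    ``r2_max`` the member with the smaller MAF is removed (tie: the one at
    the later map position).  The procedure is deterministic; ``seed`` is
    accepted for interface uniformity.
    """
    del seed  # deterministic
    maf = minor_allele_frequency(dataset.calls)
    keep = np.ones(dataset.n_variants, dtype=bool)
    chroms = dataset.variants["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = len(idx)
        starts = range(0, max(m - params.step_snps, 1), params.step_snps)
        for s in starts:
            win = idx[s:s + params.window_snps]
            win = win[keep[win]]
            if len(win) < 2:
                continue
            r2 = _pairwise_r2(dataset.calls[:, win])
            active = np.ones(len(win), dtype=bool)
            while True:
                removed_one = False
                ii, jj = np.where(np.triu(r2 > params.r2_max, k=1))
                for a, b in zip(ii, jj):
                    if active[a] and active[b]:
                        # drop the smaller-MAF member; tie -> later position
                        if maf[win[a]] < maf[win[b]]:
                            drop = a
                        elif maf[win[b]] < maf[win[a]]:
                            drop = b
                        else:
                            drop = b  # later map position
                        active[drop] = False
                        r2[drop, :] = 0.0
                        r2[:, drop] = 0.0
                        removed_one = True
                if not removed_one:
                    break
            keep[win[~active]] = False
    return dataset.variants.loc[keep, "variant_id"].tolist()
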