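"""Independent reference implementations used only for cross-checking.

Everything here is deliberately written against the *definition* of each
quantity (explicit window enumeration, full probability enumeration,
dense eigendecompositions) rather than sharing any mechanism with the
package code paths it checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln

from rohstruct.plink import MISSING
from rohstruct.roh import ROHParams, ROHSegment


# ---------------------------------------------------------------------------
# sliding-window ROH oracle
# ---------------------------------------------------------------------------

def oracle_window_states(genos: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP homozygosity state by explicit enumeration of every window."""
    genos = np.asarray(genos)
    m = len(genos)
    if m == 0:
        return np.zeros(0, dtype=bool)
    w = min(params.window_snps, m)
    windows = sliding_window_view(genos, w)              # (m - w + 1, w)
    het_counts = (windows == 1).sum(axis=1)
    mis_counts = (windows == MISSING).sum(axis=1)
    win_ok = ((het_counts <= params.max_het_per_window)
              & (mis_counts <= params.max_missing_per_window))
    n_win = len(win_ok)
    states = np.zeros(m, dtype=bool)
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, n_win - 1)
        overlapping = win_ok[lo:hi + 1]
        states[j] = overlapping.mean() >= params.window_hom_prop_min
    return states


def oracle_detect_roh(genos: np.ndarray, pos: np.ndarray, chrom: int,
                      sample_id: str, params: ROHParams) -> list[ROHSegment]:
    """Reference run construction for one chromosome: scan states one SNP at
    a time, break runs at large gaps, then apply the emission filters."""
    states = oracle_window_states(genos, params)
    segments = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        n_snps = len(run_idx)
        start, end = int(pos[run_idx[0]]), int(pos[run_idx[-1]])
        length = end - start
        if (n_snps >= params.min_snps_per_roh
                and length >= params.min_length_bp
                and length / n_snps <= params.min_density_bp_per_snp):
            segments.append(ROHSegment(sample_id, int(chrom), start, end, n_snps))

    for j, on in enumerate(states):
        if not on:
            flush(run)
            run = []
            continue
        if run and pos[j] - pos[run[-1]] > params.max_gap_bp:
            flush(run)
            run = []
        run.append(j)
    flush(run)
    return segments


# ---------------------------------------------------------------------------
# exact HWE oracle
# ---------------------------------------------------------------------------

def oracle_hwe_distribution(n: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote-count distribution from the closed-form configuration
    probability (log-factorial form), enumerated over the full support."""
    n_a = 2 * n - n_b
    m = min(n_a, n_b)
    hets = np.arange(n_b % 2, m + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logp = (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(hets + 1)
            - gammaln(n_bb + 1) + hets * np.log(2)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    return hets, probs / probs.sum()


def oracle_hwe_pvalue(n_aa: int, n_ab: int, n_bb: int,
                      tie_rtol: float = 1e-12) -> float:
    """Two-sided exact p by summing all configurations at most as probable
    as the observed one (same tie convention as the implementation)."""
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb
    hets, probs = oracle_hwe_distribution(n, min(n_b, 2 * n - n_b))
    p_obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + tie_rtol)].sum()))


# ---------------------------------------------------------------------------
# Weir & Cockerham multilocus F_ST (genotype-count form)
# ---------------------------------------------------------------------------

def oracle_fst_weir_cockerham(calls: np.ndarray, pops: np.ndarray) -> float:
    """Multilocus theta over all SNPs; missing calls excluded per SNP."""
    pops = np.asarray(pops)
    groups = np.unique(pops)
    r = len(groups)
    a_sum = d_sum = 0.0
    for j in range(calls.shape[1]):
        n_i, p_i, h_i = [], [], []
        for g in groups:
            col = calls[pops == g, j]
            col = col[col != MISSING]
            if len(col) == 0:
                break
            n_i.append(len(col))
            p_i.append(col.sum() / (2.0 * len(col)))
            h_i.append((col == 1).mean())
        else:
            n_i = np.array(n_i, dtype=float)
            p_i = np.array(p_i)
            h_i = np.array(h_i)
            n_bar = n_i.mean()
            n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
            p_bar = (n_i * p_i).sum() / n_i.sum()
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / n_i.sum()
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                                       - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                         - (r - 1) / r * s2
                                         - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2
            a_sum += a
            d_sum += a + b + c
    return a_sum / d_sum if d_sum else float("nan")


# ---------------------------------------------------------------------------
# random ROH-bearing genotype fixtures
# ---------------------------------------------------------------------------

def make_roh_fixture(rng: np.random.Generator, n_samples: int = 20,
                     n_snps: int = 3000):
    """Random genotypes with injected homozygous stretches, noise and
    missingness, on a 2-chromosome map; for detector cross-validation."""
    import pandas as pd

    per_chrom = n_snps // 2
    frames, calls_cols = [], []
    freqs = rng.uniform(0.05, 0.95, size=n_snps)
    calls = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(np.int8)
    offset = 0
    for chrom in (1, 2):
        pos = np.sort(rng.choice(np.arange(1, 30_000_001), size=per_chrom,
                                 replace=False))
        frames.append(pd.DataFrame({
            "variant_id": [f"c{chrom}_{k}" for k in range(per_chrom)],
            "chrom": chrom, "pos_bp": pos,
            "allele_a": "A", "allele_b": "B"}))
        # homozygous stretches of 0.5 - 5 Mb in random samples
        for _ in range(rng.integers(2, 8)):
            i = rng.integers(n_samples)
            start = rng.integers(1, 28_000_000)
            end = start + rng.integers(500_000, 5_000_000)
            sel = offset + np.flatnonzero((pos >= start) & (pos <= end))
            calls[i, sel] = (2 * rng.integers(0, 2, size=len(sel))).astype(np.int8)
            # sparse het/missing contamination inside the stretch
            noise = sel[rng.random(len(sel)) < 0.01]
            calls[i, noise] = 1
        offset += per_chrom
    variants = pd.concat(frames, ignore_index=True)
    miss = rng.random(calls.shape) < 0.02
    calls[miss] = MISSING
    return calls, variants
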