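"""ROH detection, F_ROH, length classes and consensus regions."""

import numpy as np
import pandas as pd
import pytest

from rohstruct import (MISSING, ROHParams, ROHSegment,
                       window_homozygosity_states, detect_roh,
                       detect_roh_sample, classify_roh_lengths, froh,
                       froh_table, roh_summary, consensus_regions)
from rohstruct.roh import map_chromosome_spans

from conftest import tiny_dataset
from oracles import oracle_window_states, oracle_detect_roh, make_roh_fixture

PARAMS = ROHParams()


def variants_1chrom(pos):
    return pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(len(pos))],
        "chrom": 1, "pos_bp": np.asarray(pos),
        "allele_a": "A", "allele_b": "B",
    })


def test_all_het_vector_has_no_homozygous_state():
    assert not window_homozygosity_states(np.ones(100, dtype=np.int8), PARAMS).any()


def test_all_hom_vector_is_fully_homozygous():
    assert window_homozygosity_states(np.zeros(100, dtype=np.int8), PARAMS).all()


def test_isolated_het_stays_inside_run():
    """One het in 100 hom SNPs: every overlapping window has <= 1 het, so
    even the het SNP keeps the homozygous state."""
    g = np.zeros(100, dtype=np.int8)
    g[50] = 1
    states = window_homozygosity_states(g, PARAMS)
    assert states.all()
    assert np.array_equal(states, oracle_window_states(g, PARAMS))


def test_short_chromosome_uses_single_truncated_window():
    g = np.zeros(10, dtype=np.int8)
    assert window_homozygosity_states(g, PARAMS).all()
    g[3] = g[7] = 1  # 2 hets in the only window: fails
    assert not window_homozygosity_states(g, PARAMS).any()


def test_detect_single_clean_segment():
    """60 hom SNPs at 25 kb spacing (span 1.475 Mb) in a het background."""
    n = 300
    pos = np.arange(n) * 25_000 + 1
    g = np.ones(n, dtype=np.int8)
    g[100:160] = 0
    segs = detect_roh_sample(g, variants_1chrom(pos), "s0", PARAMS)
    assert len(segs) == 1
    (seg,) = segs
    assert seg.n_snps == 60
    assert seg.start_bp == pos[100] and seg.end_bp == pos[159]
    assert segs == oracle_detect_roh(g, pos, 1, "s0", PARAMS)


def test_sub_megabase_run_is_rejected():
    """45 hom SNPs spanning 0.8 Mb fail the 1 Mb length floor."""
    n = 245
    pos = np.arange(n) * 18_182 + 1  # 45 SNPs span ~0.8 Mb
    g = np.ones(n, dtype=np.int8)
    g[100:145] = 0
    assert detect_roh_sample(g, variants_1chrom(pos), "s0", PARAMS) == []


def test_large_gap_splits_run_and_each_side_requalifies():
    """80 hom SNPs with a 600 kb gap in the middle: the run splits and each
    half (40 SNPs, ~1.17 Mb) must qualify on its own."""
    pos = np.concatenate([
        np.arange(40) * 30_000 + 1,
        np.arange(40) * 30_000 + 40 * 30_000 + 600_000 + 1,
    ])
    g = np.zeros(80, dtype=np.int8)
    segs = detect_roh_sample(g, variants_1chrom(pos), "s0", PARAMS)
    assert len(segs) == 2
    assert all(s.n_snps == 40 for s in segs)
    assert segs == oracle_detect_roh(g, pos, 1, "s0", PARAMS)


def test_sparse_run_fails_density_filter():
    """40 hom SNPs spaced 60 kb: span/SNP-count ratio exceeds 50 kb/SNP
    (gaps stay under the 500 kb split threshold)."""
    pos = np.arange(40) * 60_000 + 1
    g = np.zeros(40, dtype=np.int8)
    assert detect_roh_sample(g, variants_1chrom(pos), "s0", PARAMS) == []


def test_detector_matches_bruteforce_oracle_on_random_fixtures():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        calls, variants = make_roh_fixture(rng, n_samples=5, n_snps=1000)
        ds = tiny_dataset(calls, chrom=variants["chrom"], pos=variants["pos_bp"])
        got = detect_roh(ds, PARAMS)
        expected = []
        for i, sid in enumerate(ds.samples["sample_id"]):
            for chrom in (1, 2):
                sel = ds.variants["chrom"].to_numpy() == chrom
                expected.extend(oracle_detect_roh(
                    ds.calls[i, sel], ds.variants["pos_bp"].to_numpy()[sel],
                    chrom, str(sid), PARAMS))
        assert got == expected


def test_raising_min_length_never_adds_segments():
    rng = np.random.default_rng(7)
    calls, variants = make_roh_fixture(rng, n_samples=6, n_snps=1200)
    ds = tiny_dataset(calls, chrom=variants["chrom"], pos=variants["pos_bp"])
    counts = [len(detect_roh(ds, ROHParams(min_length_bp=mb * 1_000_000)))
              for mb in (1, 2, 4, 8)]
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("length_mb, label", [
    (3.5, "2-4 Mb"), (2.0, "2-4 Mb"), (1.0, "1-2 Mb"),
    (15.999, "8-16 Mb"), (16.0, ">16 Mb"), (64.4, ">16 Mb"),
])
def test_length_classification(length_mb, label):
    seg = ROHSegment("s", 1, 1, int(length_mb * 1e6) + 1, 100)
    counts = classify_roh_lengths([seg])
    assert counts[label] == 1
    assert sum(counts.values()) == 1


def test_length_below_detector_floor_is_a_contract_violation():
    with pytest.raises(ValueError):
        classify_roh_lengths([ROHSegment("s", 1, 1, 500_000, 40)])


def test_froh_no_segments_is_zero():
    v = variants_1chrom([1, 1_000_000])
    assert froh([], v, "s0").froh_genome == 0.0


def test_froh_arithmetic():
    """125.2 Mb of ROH on a 2504 Mb map-covered genome gives 0.05."""
    v = variants_1chrom([1, 2_504_000_001])
    segs = [ROHSegment("s0", 1, 1, 125_200_001, 5000)]
    assert froh(segs, v, "s0").froh_genome == pytest.approx(0.05)


def test_froh_segment_on_unmapped_chromosome_errors():
    v = variants_1chrom([1, 1_000_000])
    with pytest.raises(ValueError, match="chromosome"):
        froh([ROHSegment("s0", 5, 1, 2_000_000, 50)], v, "s0")


def test_froh_coverage_identity():
    """Genome coverage equals the span-weighted sum of per-chromosome
    coverages: froh_genome * L_total == sum_c froh_chrom[c] * L_c."""
    rng = np.random.default_rng(12)
    calls, variants = make_roh_fixture(rng, n_samples=4, n_snps=1500)
    ds = tiny_dataset(calls, chrom=variants["chrom"], pos=variants["pos_bp"])
    segs = detect_roh(ds, PARAMS)
    spans = map_chromosome_spans(ds.variants)
    l_total = sum(spans.values())
    for sid in ds.samples["sample_id"].astype(str):
        res = froh(segs, ds.variants, sid)
        lhs = res.froh_genome * l_total
        rhs = sum(res.froh_by_chrom[c] * spans[c] for c in spans)
        assert lhs == pytest.approx(rhs, abs=1e-6)


def _seg(sid, start_mb, end_mb, chrom=1):
    return ROHSegment(sid, chrom, int(start_mb * 1e6), int(end_mb * 1e6), 100)


def _consensus_fixture(n_carriers, n_total=10):
    """n_carriers of n_total individuals share a ROH over [2, 4] Mb."""
    pos = np.arange(1, 6_000_002, 100_000)
    v = variants_1chrom(pos)
    ids = [f"s{i}" for i in range(n_total)]
    segs = [_seg(ids[i], 2.0 + 1e-6, 4.0 + 1e-6) for i in range(n_carriers)]
    groups = pd.Series("AS", index=ids)
    return segs, groups, v


def test_consensus_region_emitted_above_strict_threshold():
    segs, groups, v = _consensus_fixture(4)
    regions = consensus_regions(segs, groups, v, support_min=0.30)
    assert len(regions) == 1
    assert regions[0].support == pytest.approx(0.4)
    assert regions[0].subgroup_set == ("AS",)


def test_consensus_region_at_exact_threshold_not_emitted():
    """'More than 30%' is strict: 3 of 10 carriers do not qualify."""
    segs, groups, v = _consensus_fixture(3)
    assert consensus_regions(segs, groups, v, support_min=0.30) == []


def test_disjoint_private_roh_yield_no_consensus():
    pos = np.arange(1, 10_000_002, 100_000)
    v = variants_1chrom(pos)
    segs = [_seg("s0", 1.0, 2.5), _seg("s1", 4.0, 5.5), _seg("s2", 7.0, 8.5)]
    groups = pd.Series("AS", index=[f"s{i}" for i in range(10)])
    assert consensus_regions(segs, groups, v, support_min=0.30) == []


def test_consensus_support_zero_single_individual_returns_own_roh():
    pos = np.arange(1, 6_000_002, 50_000)
    v = variants_1chrom(pos)
    seg = _seg("s0", 1.0 + 1e-6, 3.0 + 1e-6)
    groups = pd.Series("AS", index=["s0"])
    regions = consensus_regions([seg], groups, v, support_min=0.0)
    assert len(regions) == 1
    # snapped to the SNP grid covering the segment
    assert regions[0].start_bp <= seg.start_bp + 50_000
    assert regions[0].end_bp >= seg.end_bp - 50_000


def test_identical_regions_merge_across_subgroups():
    pos = np.arange(1, 6_000_002, 100_000)
    v = variants_1chrom(pos)
    ids_a = [f"a{i}" for i in range(4)]
    ids_b = [f"b{i}" for i in range(4)]
    segs = [_seg(sid, 2.0 + 1e-6, 4.0 + 1e-6) for sid in ids_a + ids_b[:2]]
    groups = pd.Series(["AS"] * 4 + ["DM"] * 4, index=ids_a + ids_b)
    regions = consensus_regions(segs, groups, v, support_min=0.30)
    assert len(regions) == 1
    assert set(regions[0].subgroup_set) == {"AS", "DM"}


def test_roh_summary_zero_roh_individuals_count_in_denominator():
    ids = [f"s{i}" for i in range(10)]
    groups = pd.Series("AS", index=ids)
    segs = []
    for i in range(5):  # 5 individuals carry 10 short ROH each; 5 carry none
        segs.extend(_seg(ids[i], 10 + k * 2, 11.5 + k * 2) for k in range(10))
    table = roh_summary(segs, groups)
    assert table.loc[0, "mean_n_roh"] == pytest.approx(5.0)
    assert table.loc[0, "mean_n_roh_1-2 Mb"] == pytest.approx(5.0)
    assert table.loc[0, "n_individuals"] == 10
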