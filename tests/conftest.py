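import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rohstruct import GenotypeDataset, SimParams, simulate_subpopulations
from rohstruct.simulate import CATTLE_CHROM_LENGTHS_BP

#: 1/10-scale autosome map (~250 Mb) used wherever a dense map is needed fast.
SCALED_CHROM_LENGTHS = tuple(int(l / 10) for l in CATTLE_CHROM_LENGTHS_BP)


def tiny_dataset(calls, chrom=None, pos=None, sample_ids=None) -> GenotypeDataset:
    """Hand-rolled dataset from a dosage matrix, for unit fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    ids = [f"s{i}" for i in range(n)] if sample_ids is None else list(sample_ids)
    samples = pd.DataFrame({
        "sample_id": ids, "subgroup": "AS", "herd_id": "H1", "sire_id": "S1",
        "birth_year": pd.array([2015] * n, dtype="Int64"),
        "panel_density": pd.array([54609] * n, dtype="Int64"),
    })
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom, "pos_bp": pos, "allele_a": "A", "allele_b": "B",
    })
    ds = GenotypeDataset(samples, variants, calls)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def small_cohort():
    """3 subgroups x 30 cows, 4000 SNPs, mild divergence; shared read-only."""
    params = SimParams(n_pops=3, n_per_pop=30, n_snps=4000, fst=0.05, seed=11,
                      chrom_lengths_bp=SCALED_CHROM_LENGTHS)
    dataset, truth = simulate_subpopulations(params)
    return dataset, truth
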