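"""Shared fixtures: one small synthetic cohort reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from denovotrio import denovo_calling
from denovotrio.core import GenomeModel
from denovotrio.synthetic_cohort import CohortConfig, simulate_cohort, write_cohort

SMALL_CONFIG = CohortConfig(
    n_families=30, seed=42,
    chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
    background_sites_per_family=50,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, out)
    return out


@pytest.fixture(scope="session")
def small_calls(small_cohort_dir):
    """(calls, callability) from running the caller over the small cohort."""
    return denovo_calling.cohort_call_and_callability(small_cohort_dir)


@pytest.fixture(scope="session")
def tiny_genome():
    """A fixed 60 bp single-chromosome genome for classification tests."""
    seq = ("ACGTACGGTACCGGTAACGTTTACGCGTATCCGGAATTCCGGAACGTACGTTAGCATCGA")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    return GenomeModel(chrom_names=["chrT"], sequence={"chrT": arr})


def make_mutations(positions, individuals, kind="SNV", chrom="chr1",
                   ref="A", alt="G"):
    """Convenience builder for bare mutation tables used in clustering tests."""
    n = len(positions)
    ind = individuals if not isinstance(individuals, str) else [individuals] * n
    df = pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": list(positions),
        "ref_allele": [ref] * n,
        "alt_allele": [alt] * n,
        "kind": [kind] * n if isinstance(kind, str) else list(kind),
        "individual_id": list(ind),
        "family_id": list(ind),
        "concat_pos": list(positions),
    })
    return df.sort_values("concat_pos", kind="mergesort").reset_index(drop=True)
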