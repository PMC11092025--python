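"""Shared fixtures: small deterministic matrices and synthetic datasets."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germscan.model import GenotypeMatrix, PopulationTable, HOM_REF, HET, HOM_ALT, MISSING
from germscan import synthpop as sp


def make_matrix(calls: np.ndarray, accessions=None, chrom="Chr01", start=100,
                spacing=1000) -> GenotypeMatrix:
    """Matrix of SNPs at regular positions from a raw call array (V x N)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_acc = calls.shape
    if accessions is None:
        accessions = [f"A{i:03d}" for i in range(n_acc)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_var,
            "pos": [start + i * spacing for i in range(n_var)],
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
            "vclass": ["SNP"] * n_var,
        }
    )
    return GenotypeMatrix(variants, list(accessions), calls)


def two_pop_table(matrix: GenotypeMatrix, n_wild: int) -> PopulationTable:
    labels = {}
    for i, acc in enumerate(matrix.accessions):
        labels[acc] = "wild" if i < n_wild else "cultivated"
    return PopulationTable(labels)


@pytest.fixture(scope="session")
def demo_dataset():
    """One moderately sized dataset reused by read-only tests."""
    return sp.simulate_dataset(sp.default_config(7))


@pytest.fixture(scope="session")
def tiny_config():
    return sp.SimConfig(
        seed=11,
        n_wild=40,
        n_cult=50,
        n_hybrids=4,
        n_duplicates=1,
        n_chrom=1,
        chrom_len=100_000,
        snp_density=0.001,
        indel_density=0.0001,
        planted_windows=[sp.PlantedWindow("Chr01", 40_001, 60_000, "type1", n_snps=40)],
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return sp.simulate_dataset(tiny_config)
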