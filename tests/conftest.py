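"""Shared fixtures and tiny genotype builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snpdiv.datamodel import GenotypeMatrix


def make_gm(
    dosage,
    positions=None,
    chromosomes=None,
    populations=None,
    spacing_bp: int = 10_000,
) -> GenotypeMatrix:
    """Construct a GenotypeMatrix from a dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * spacing_bp
    if chromosomes is None:
        chromosomes = ["1"] * m
    variants = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{i}" for i in range(n)],
            "population": populations if populations is not None else "pop0",
        }
    )
    return GenotypeMatrix(samples, variants, dosage)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_pool():
    """A small founder pool reused by several simulation-backed tests."""
    from snpdiv.sim import SimConfig, simulate_founders

    cfg = SimConfig(
        n_snps=1200, n_chromosomes=4, chrom_length_mb=50, ne=60,
        n_generations=0, seed=7,
    )
    return simulate_founders(cfg)
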