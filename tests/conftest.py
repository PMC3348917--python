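"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stratpca as sp
from stratpca.sim import LDBlockSpec

# scaled-down analog of the headline cohort: structure still resolves
# (cline on PC1, local LD blocks on middle PCs) but each build takes ~0.2 s
SMALL_BLOCKS = (
    LDBlockSpec(280, 292, "cline_linked", 0.8),     # chromosome "2"
    LDBlockSpec(1080, 1092, "local_only", 0.8),     # chromosome "6"
    LDBlockSpec(1480, 1490, "inversion_like", 0.8),  # chromosome "8"
)


def small_config(seed: int = 1, **overrides) -> sp.SimConfig:
    base = dict(n_per_site=(150,) * 4, n_snps=2000, ld_blocks=SMALL_BLOCKS)
    base.update(overrides)
    return sp.headline_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_cohort():
    genotypes, truth = sp.simulate_dataset(small_config(seed=1))
    return genotypes, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    genotypes, _ = small_cohort
    return sp.fit_pca(genotypes, k=10)


def toy_genotypes(n: int, p: int, seed: int = 0, freq: float = 0.4) -> sp.GenotypeMatrix:
    """Unstructured random genotype matrix for I/O and scan null tests."""
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freq, size=(n, p)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "id": [f"s{i:04d}" for i in range(p)],
            "chromosome": "1",
            "position": np.arange(1, p + 1) * 100,
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"i{i:04d}" for i in range(n)],
            "site": "X",
            "status": np.where(rng.random(n) < 0.5, "case", "control"),
        }
    )
    return sp.GenotypeMatrix(dosages, snps, samples)
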