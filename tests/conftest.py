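"""Shared fixtures: small synthetic cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

from sepqtl.io import build_covariates
from sepqtl.synth import simulate_cohort, simulate_genotypes


@pytest.fixture(scope="session")
def small_geno():
    return simulate_genotypes(
        200, 40, maf_range=(0.2, 0.45), ld_rho=0.2, block_size=20, seed=11
    )


@pytest.fixture(scope="session")
def cis_cohort(small_geno):
    """Cohort with one strong planted cis effect (gene G0010, snp00008)."""
    truth = {
        "cis_effects": [
            {"gene": "G0010", "snp": "snp00008", "beta": 0.8, "signal_rank": 1}
        ]
    }
    bundle = simulate_cohort(small_geno, {"n_genes": 300}, truth, seed=12)
    samples = build_covariates(bundle.expression, bundle.samples)
    return bundle, samples


@pytest.fixture(scope="session")
def null_cohort(small_geno):
    """Pure-noise cohort (no planted effects)."""
    bundle = simulate_cohort(small_geno, {"n_genes": 120}, {}, seed=13)
    samples = build_covariates(bundle.expression, bundle.samples)
    return bundle, samples


@pytest.fixture
def rng():
    return np.random.default_rng(0)
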