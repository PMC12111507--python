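"""Shared fixtures: simulated cohorts with known ground truth.

Session-scoped so the heavier cohorts (null calibration, planted effects) are
generated and analyzed once and reused across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from eopmeth.ewas import fit_cpg_association
from eopmeth.preprocess import beta_to_m, estimate_surrogate_variables
from eopmeth.simulate import SimConfig, generate_cohort


def run_ewas(beta, sheet, sv_k=5, mode="methylation_as_outcome"):
    """Standard covariate-adjusted EWAS: group + age + sex + SV1..SVk."""
    m = beta_to_m(beta)
    sv = estimate_surrogate_variables(m, sheet["group"], k=sv_k)
    covs = pd.concat([sheet[["age", "sex"]], sv], axis=1)
    return fit_cpg_association(beta, sheet["group"], covs, mode=mode)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale 12/11 cohort with eight planted CpGs (default config)."""
    cfg = SimConfig(n_cpgs=2000, seed=7)
    beta, sheet, truth = generate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """n=200 cohort with 20 causal CpGs of beta-scale effect 0.15."""
    cfg = SimConfig(n_cases=100, n_controls=100, n_cpgs=2000, n_causal=20,
                    effect_delta=0.15, seed=11)
    beta, sheet, truth = generate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def planted_ewas(planted_cohort):
    _, beta, sheet, truth = planted_cohort
    return run_ewas(beta, sheet), truth


@pytest.fixture(scope="session")
def null_cohort():
    """n=100 cohort with no planted group effect (5000 CpGs)."""
    cfg = SimConfig(n_cases=50, n_controls=50, n_cpgs=5000, n_causal=0, seed=3)
    beta, sheet, truth = generate_cohort(cfg)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def null_ewas(null_cohort):
    _, beta, sheet, _ = null_cohort
    return run_ewas(beta, sheet)
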