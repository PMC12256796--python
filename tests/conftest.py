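import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

import xdosage as xd


@pytest.fixture(scope="session")
def fullxci_sumstats():
    """Direct-path summary statistics: full XCI, both genome regions."""
    cfg = xd.SimConfig(seed=11, n_males=20_000, n_females=20_000,
                       m_auto=1500, m_x=500, h2_auto=0.2, h2_x=None,
                       causal_fraction_auto=0.1, causal_fraction_x=0.1)
    return cfg, xd.simulate_sumstats_direct(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Individual-level cohort small enough for per-test OLS reruns."""
    cfg = xd.SimConfig(seed=7, n_males=4000, n_females=4000,
                       m_auto=300, m_x=200, h2_auto=0.15, h2_x=0.05,
                       causal_fraction_auto=0.2, causal_fraction_x=0.2)
    return cfg, xd.simulate_cohort(cfg)


def make_mixture_pairs(pi, sigma2, n, se=0.02, alpha=2.0, seed=0):
    """Draw scaled effect pairs straight from the four-component model."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(4, size=n, p=pi)
    z = rng.standard_normal(n) * np.sqrt(sigma2)
    bf = np.where(comp == 1, alpha * z, np.where(comp == 0, 0.0, z))
    bm = np.where(comp == 3, alpha * z, np.where(comp == 0, 0.0, z))
    return pd.DataFrame({
        "SNP": [f"v{i}" for i in range(n)],
        "BETA_F": bf + se * rng.standard_normal(n),
        "BETA_M": bm + se * rng.standard_normal(n),
        "SE_F": se, "SE_M": se,
    }), comp


@pytest.fixture(scope="session")
def mixture_pairs_factory():
    return make_mixture_pairs
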