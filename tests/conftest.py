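import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_table(values: dict) -> pd.DataFrame:
    """Long table from {(genotype, env, rep): value} for a single trait."""
    rows = [{"genotype": g, "environment": e, "replicate": str(r),
             "trait": "T", "value": float(v)}
            for (g, e, r), v in values.items()]
    return pd.DataFrame(rows)


@pytest.fixture
def two_by_two_table() -> pd.DataFrame:
    """2 genotypes x 2 environments x 2 replicates; A all 1, B all 3."""
    vals = {}
    for e in ("E1", "E2"):
        for r in (1, 2):
            vals[("A", e, r)] = 1.0
            vals[("B", e, r)] = 3.0
    return make_table(vals)


@pytest.fixture
def balanced_sim():
    """A balanced g=30, t=2, r=2 single-trait dataset with interior components."""
    from wuequant.synthdata import SimulationConfig, simulate_trait_table

    cfg = SimulationConfig(
        n_genotypes=30, n_environments=2, n_replicates=2,
        trait_names=["T"], mu=np.array([10.0]),
        env_effects=np.array([[0.0], [1.0]]),
        Sigma_g=np.eye(1) * 2.0, Sigma_ge=np.eye(1) * 1.0,
        Sigma_e=np.eye(1) * 4.0, seed=42)
    return simulate_trait_table(cfg)


@pytest.fixture
def bivariate_sim():
    """Balanced g=30 pair of correlated traits (r_g = -0.5)."""
    from wuequant.synthdata import SimulationConfig, simulate_trait_table

    Sg = np.array([[2.0, -0.5 * np.sqrt(2.0)], [-0.5 * np.sqrt(2.0), 1.0]])
    # sizeable G x E block keeps all stratum estimates comfortably interior
    cfg = SimulationConfig(
        n_genotypes=30, n_environments=2, n_replicates=2,
        trait_names=["T1", "T2"], mu=np.array([5.0, -2.0]),
        env_effects=np.zeros((2, 2)),
        Sigma_g=Sg, Sigma_ge=np.array([[1.5, 0.45], [0.45, 1.5]]),
        Sigma_e=np.array([[3.0, 0.8], [0.8, 2.0]]), seed=7)
    return simulate_trait_table(cfg)
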