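import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from duomr import SimulationConfig, simulate_study
from duomr.assoc import HaplotypeFit

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_study():
    """Moderate-size simulated duo study shared across read-only tests."""
    cfg = SimulationConfig(n_pregnancies=4000, n_snps=40, seed=123)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_config():
    """Generator configuration with every planted effect switched off."""
    return SimulationConfig(
        n_pregnancies=2000,
        n_snps=50,
        maternal_effect=0.0,
        maternal_effect_bw=0.0,
        fetal_effect_per_score=0.0,
        fetal_effect_bw_per_score=0.0,
        fetal_drive_effect=0.0,
        confounding_gest=0.0,
        confounding_bw=0.0,
        seed=0,
    )


def make_fit(beta, cov=None, outcome="y", family="linear", n=1000):
    beta = np.asarray(beta, dtype=float)
    if cov is None:
        cov = np.eye(3) * 0.01
    return HaplotypeFit(
        outcome=outcome,
        dataset="all",
        beta=beta,
        cov=np.asarray(cov, dtype=float),
        n_used=n,
        family=family,
    )
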