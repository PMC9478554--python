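import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from woolgs import SimConfig, simulate_population, stabilize, vanraden_grm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_population():
    """A compact family-structured population shared across test modules."""
    cfg = SimConfig(
        n_individuals=200, n_markers=2000, n_qtl=100,
        n_sires=10, n_dams=40, seed=12345,
    )
    geno, pheno, truth = simulate_population(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_grm(small_population):
    _, geno, _, _ = small_population
    return vanraden_grm(geno, on_monomorphic="drop")


@pytest.fixture(scope="session")
def small_grm_stable(small_grm):
    return stabilize(small_grm)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
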