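import numpy as np
import pytest

from atrcn import Cohort, ExpressionMatrix, SimulationConfig, SurvivalTable, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_survival(times, events, ids=None, covariates=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(ids, np.asarray(times, float), np.asarray(events, int), covariates)


def make_cohort(name, values, times, events):
    """Tiny cohort from a genes x samples array."""
    values = np.asarray(values, float)
    n_genes, n_samples = values.shape
    ids = [f"{name}_s{i}" for i in range(n_samples)]
    expr = ExpressionMatrix([f"g{i}" for i in range(n_genes)], ids, values)
    return Cohort(name, expr, make_survival(times, events, ids=ids))


def random_survival(rng, n, censor_frac=0.3):
    t = rng.exponential(10.0, n) + 0.01
    e = (rng.uniform(size=n) > censor_frac).astype(int)
    if e.sum() == 0:
        e[int(np.argmin(t))] = 1
    return make_survival(t, e)


@pytest.fixture(scope="session")
def small_study():
    """Six-cohort, two-family synthetic study shared across tests."""
    cfg = SimulationConfig(
        n_cohorts=6, n_families=2, n_samples=100, n_genes=40,
        latent_rank=4, censor_rate=0.3, family_shift=3.0, seed=42,
    )
    return simulate_study(cfg)
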