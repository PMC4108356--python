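import numpy as np
import pytest

from firefreq import (
    ClassSpec,
    DiscreteLognormalParams,
    SimulationConfig,
    simulate_history,
)
from firefreq.datasets import JALAPAO_CLASSES


@pytest.fixture(scope="session")
def table_params() -> dict[str, DiscreteLognormalParams]:
    """Published (mu, sigma) per land-cover class."""
    return {code: c.params for code, c in JALAPAO_CLASSES.items()}


@pytest.fixture(scope="session")
def ss_params(table_params) -> DiscreteLognormalParams:
    return table_params["SS"]


@pytest.fixture(scope="session")
def small_grid():
    """A small single-class simulated landscape (shrub-savanna regime)."""
    cfg = SimulationConfig(
        classes=[ClassSpec("SS", DiscreteLognormalParams(0.82, 0.66), 1.0)],
        shape=(30, 30),
        cell_size=500.0,
        burn_in=50,
        seed=2024,
    )
    return simulate_history(cfg)


def draw_intervals(params: DiscreteLognormalParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """iid draws from the discrete lognormal via its pmf on a truncated support."""
    from firefreq import interval_pmf

    ts = np.arange(1, 1000)
    pmf = np.asarray(interval_pmf(ts, params))
    return rng.choice(ts, size=n, p=pmf / pmf.sum())
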