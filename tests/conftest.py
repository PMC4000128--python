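import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from progsig import (
    ExpressionMatrix,
    SimulationConfig,
    score_all,
    simulate_cohort,
)

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """One study-scale synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def score_table(cohort):
    return score_all(cohort.expression, cohort.signatures, cohort.clinical)


@pytest.fixture()
def small_matrix():
    """3 genes x 4 samples, handwritten values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 1.5, 2.5], [-1.0, 0.0, 1.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


def simulate_exponential(rng, n, beta, *, base_rate=0.1, censor_rate=0.05):
    """Plain exponential survival with a unit-variance covariate."""
    z = rng.standard_normal(n)
    t = rng.exponential(1.0 / (base_rate * np.exp(beta * z)))
    c = rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf)
    return z, np.minimum(t, c), (t <= c).astype(int)


def simulate_piecewise(rng, n, schedule, *, base_rate=0.1, horizon=10.0, censor_rate=0.03):
    """Piecewise log-HR schedule [(start, end, beta), ...] on a N(0,1) covariate."""
    z = rng.standard_normal(n)
    target = rng.exponential(1.0, n)
    t = np.full(n, np.inf)
    remaining = target.copy()
    done = np.zeros(n, dtype=bool)
    for a, b, beta in schedule:
        rate = base_rate * np.exp(beta * z)
        seg = rate * (b - a) if np.isfinite(b) else np.full(n, np.inf)
        hit = ~done & (remaining <= seg)
        t[hit] = a + remaining[hit] / rate[hit]
        done |= hit
        remaining = remaining - np.where(done, 0.0, rate * (b - a if np.isfinite(b) else 0.0))
    c = np.minimum(
        rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf),
        horizon,
    )
    return z, np.minimum(t, c), (t <= c).astype(int)
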