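import numpy as np
import pandas as pd
import pytest

from stagebench import PredictionSet, default_params, sample_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return sample_cohort(default_params(n=300, seed=11))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    return sample_cohort(default_params(n=10000, seed=7))


def make_predictions(prob, label, model="toy") -> PredictionSet:
    prob = np.asarray(prob, dtype=float)
    label = np.asarray(label, dtype=int)
    n = len(prob)
    return PredictionSet(
        ids=np.array([f"P{i:05d}" for i in range(n)], dtype=object),
        prob=prob,
        label=label,
        fold=np.ones(n, dtype=int),
        model=model,
    )


@pytest.fixture()
def random_predictions():
    """Factory for random prediction sets with both classes present."""

    def factory(n, seed, n_distinct=None):
        rng = np.random.default_rng(seed)
        prob = rng.random(n)
        if n_distinct is not None:
            grid = np.linspace(0.05, 0.95, n_distinct)
            prob = grid[rng.integers(0, n_distinct, size=n)]
        label = rng.integers(0, 2, size=n)
        label[0], label[1] = 0, 1  # guarantee both classes
        return make_predictions(prob, label)

    return factory
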