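import numpy as np
import pytest

import zonewear as zw
from zonewear.experiments import dataclass_replace


def scaled_cohort_config(minutes: float, **kw) -> zw.CohortConfig:
    """Cohort config with all temporal parameters scaled to `minutes`."""
    f = minutes / 75.0
    base = dict(
        session_minutes=minutes,
        dwell_in_min=8.0 * f,
        dwell_out_min=10.0 * f,
        verbose_reemit_min=2.5 * f,
        latency_mean_s=5.0 * f,
        latency_sd_s=2.0 * f,
        time_scale=f,
    )
    base.update(kw)
    return dataclass_replace(zw.CohortConfig(), **base)


@pytest.fixture(scope="session")
def tiny_cohort() -> zw.Cohort:
    """4-minute cohort for cheap structural tests."""
    cohort = zw.generate_cohort(scaled_cohort_config(4.0), seed=11)
    zw.build_windows(cohort, stride=5)
    return cohort


@pytest.fixture(scope="session")
def tiny_player(tiny_cohort):
    return tiny_cohort.players[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_windows(n: int, seed: int, sep: float = 2.0, window: int = 50, dim: int = 12):
    """Two Gaussian classes, separable in the channel means by `sep` sds."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(np.int8)
    X = rng.standard_normal((n, window, dim)).astype(np.float32)
    shift = rng.standard_normal(dim)
    shift = sep * shift / np.linalg.norm(shift)
    X[y == 1] += shift.astype(np.float32)
    return X, y
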