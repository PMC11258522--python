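import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MIDNIGHT = pd.Timestamp("2024-01-01 00:00")


@pytest.fixture
def midnight():
    return MIDNIGHT


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def week_epochs(rng, midnight):
    """A 7-day rhythmic epoch series: rectified-cosine days plus noise."""
    from actirhythm import EpochSeries

    t = (np.arange(7 * 1440) % 1440) / 60.0
    base = 2.0 + 40.0 * np.maximum(0.0, np.cos(2 * np.pi * (t - 14.0) / 24.0))
    counts = np.maximum(base + rng.normal(0, 1.5, base.size), 0.0)
    return EpochSeries(midnight, counts)
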