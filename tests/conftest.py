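import numpy as np
import pytest

from arspawner import Dataset, TimeSeries, generate_feature_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Two easy classes, four short series each, two subjects."""
    return generate_feature_series(
        n_classes=2, n_per_class=4, n_dims=2, length_range=(8, 14),
        separation=2.0, noise=0.05, n_subjects=2, seed=7,
    )


@pytest.fixture
def constant_series():
    """Three constant single-dim series at levels 0, 1, 2, length 5.

    All pairwise DTW distances are computable by hand: a constant series at
    level a vs one at level b of equal length L costs (a-b)^2 * L.
    """

    def make(level, sid):
        return TimeSeries(
            values=np.full((5, 1), float(level)), label="k",
            subject=f"s{sid}", series_id=f"const-{sid}",
        )

    return Dataset([make(0, 0), make(1, 1), make(2, 2)], name="const")
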