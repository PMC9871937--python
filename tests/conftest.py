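import numpy as np
import pytest

from nvcoupling.images import BoldSeries, MotionTrace
from nvcoupling.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Three subjects per group on a small grid; fast to generate."""
    return CohortSpec(
        n_per_group={"A-LHON": 3, "C-LHON": 3, "HC": 3},
        grid_shape=(16, 16, 12),
        seed=11,
    )


def make_bold(data, tr_s=2.0, **kw):
    return BoldSeries(data=np.asarray(data, float), tr_s=tr_s, **kw)


@pytest.fixture
def still_motion():
    def _make(t):
        return MotionTrace(params=np.zeros((t, 6)))

    return _make
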