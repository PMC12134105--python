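import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cysredox.synthetic_data import make_meta

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def meta10():
    """10 tumor/healthy pairs (20 samples)."""
    return make_meta(10)


@pytest.fixture
def null_matrix(meta10):
    """1000 features x 20 samples of pure N(0,1) noise, no group effect."""
    rng = np.random.default_rng(42)
    cols = [m.sample_id for m in meta10]
    return pd.DataFrame(rng.normal(size=(1000, len(cols))), columns=cols)
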