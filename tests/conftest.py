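import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """Two animals × two plants: a1 visits only p1; a2 visits both."""
    return pd.DataFrame([[2, 0], [1, 1]], index=["a1", "a2"], columns=["p1", "p2"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
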