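import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from swarmdx.synthdata import SynthSpec, generate_hd_like, generate_sequences
from swarmdx.table import FeatureTable


@pytest.fixture(scope="session")
def hd_dataset():
    """Default 303x13 cohort with four planted informative features."""
    return generate_hd_like(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def separable_sequences():
    """Well-separated two-class 1-D sequence fixture."""
    X, y = generate_sequences(n=100, length=8, separation=3.0, seed=1)
    cols = [f"t{i}" for i in range(X.shape[1])]
    return FeatureTable(pd.DataFrame(X, columns=cols), y, positive=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
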