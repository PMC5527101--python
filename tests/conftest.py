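import numpy as np
import pytest

from genppc import tasks as T


@pytest.fixture(scope="session")
def cc_spec():
    return T.make_tuning("cc")


@pytest.fixture(scope="session")
def wide_spec():
    """Dense, wide Gaussian tiling: the regime where the closed forms are
    exact (population-summed rate flat over the stimulus range)."""
    return T.make_tuning("cc", {"preferred": np.linspace(-60, 60, 121)})


@pytest.fixture(scope="session")
def cc_batch_small():
    return T.generate_trials("cc", "all_g", 200, seed=42)
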