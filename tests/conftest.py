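import numpy as np
import pytest

import myorecovery as mr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One mixed-class phantom slide with exact ground truth."""
    return mr.generate_tissue_phantom(
        mr.PhantomConfig(size=(256, 256), target_proportions=(0.4, 0.2, 0.2, 0.2), seed=7)
    )


@pytest.fixture(scope="session")
def phantom_series():
    """One phantom slide per recovery day (small canvases for speed)."""
    return mr.phantom_day_series(size=(384, 384), seed=11)
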