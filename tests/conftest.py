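import numpy as np
import pytest

import gofshrink as gs

# Default-scope calibration curves are expensive; compute once per session.
# These are the same scope/seed the pipelines use, so get_calibrated_curve
# hits its own cache as well.


@pytest.fixture(scope="session")
def dwt_curve():
    return gs.get_calibrated_curve("dwt", wavelet="db8", levels=5, window_side=5)


@pytest.fixture(scope="session")
def dtcwt_curve():
    return gs.get_calibrated_curve("dtcwt", wavelet="db8", levels=5, window_side=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom256():
    return gs.make_phantom("piecewise_constant_shapes", 256, seed=1)
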