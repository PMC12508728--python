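import numpy as np
import pytest

from hydromark import LtiParams, RectShape, TrapezoidShape


@pytest.fixture
def liver_params():
    # published 0.5 L liver dynamics with a calibrated-scale gain
    return LtiParams(gain=147.8, tau=2614.0, delay=758.0, baseline=740.0), RectShape(1303.0)


@pytest.fixture
def spleen_params():
    return (
        LtiParams(gain=50.0, tau=616.0, delay=609.0, baseline=1300.0),
        TrapezoidShape(267.0, 992.0, 129.0),
    )


@pytest.fixture
def t1_schedule():
    # 5-min cadence from -10 to 70 min, skipping the ingestion instant
    s = np.arange(-600.0, 4201.0, 300.0)
    return s[s != 0]
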