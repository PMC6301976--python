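import numpy as np
import pytest

import reefcast as rc


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def const_temp():
    """Constant 25.49 degC: no seasonality, no trend."""
    return rc.TemperatureModel(i_ave=45.0, a1=0.0, a2=0.0, a3=25.49, lam=0.0, t0=2005.0)


@pytest.fixture
def empty_schedule():
    def make(horizon=(2005.0, 2035.0)):
        return rc.EventSchedule(events=(), horizon=horizon, config=rc.ScheduleConfig())

    return make
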