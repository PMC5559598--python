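import numpy as np
import pytest

from dcmrf import presets
from dcmrf.mrf import DictionaryGrid, build_dictionary, make_default_schedule


@pytest.fixture(scope="session")
def short_schedule():
    """An 800-excitation default schedule (~11 s train): short enough for
    fast tests, long enough to encode the full T1/T2 range."""
    return make_default_schedule(n=800, baseline_tr=12.0, seed=11)


@pytest.fixture(scope="session")
def coarse_dictionary(short_schedule):
    """Coarse-grid dictionary shared across matching tests."""
    return build_dictionary(DictionaryGrid.coarse(), short_schedule, n_states=60)


@pytest.fixture
def water_60mhz():
    return presets.WATER_60MHZ


@pytest.fixture
def agents_60mhz():
    return presets.GD_60MHZ, presets.MN_60MHZ
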