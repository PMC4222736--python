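import numpy as np
import pytest

import mplv


@pytest.fixture(scope="session")
def subject_series():
    """The packaged single-subject exercise series (9 stages, 98-169 bpm)."""
    return mplv.load_fixture("table3")


@pytest.fixture(scope="session")
def subject_fits(subject_series):
    return mplv.fit_series(subject_series)


@pytest.fixture(scope="session")
def valve_geometry():
    return mplv.load_fixture("table1")


@pytest.fixture(scope="session")
def materials():
    return mplv.load_fixture("table2")


@pytest.fixture(scope="session")
def calibration(subject_series):
    """Full multistart calibration against the packaged subject (slow)."""
    return mplv.calibrate(subject_series)
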