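import numpy as np
import pytest

from stallox import simkit
from stallox.records import AcquisitionConfig


@pytest.fixture(scope="session")
def calib():
    return simkit.default_calibration()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_measurement(arrival_times_us, cycle_index, acq, weights=None, **kw):
    """Hand-built PointMeasurement for deterministic unit tests."""
    from stallox.records import PointMeasurement

    return PointMeasurement(
        capillary_id=kw.pop("capillary_id", "cap"),
        visit_index=kw.pop("visit_index", 0),
        visit_time_s=kw.pop("visit_time_s", 0.0),
        arrival_times_us=np.asarray(arrival_times_us, dtype=float),
        cycle_index=np.asarray(cycle_index, dtype=int),
        acq=acq,
        weights=weights,
        **kw,
    )
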