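import numpy as np
import pytest

import pftrace as pt


@pytest.fixture
def zones3() -> pt.ZoneSystem:
    """Reference three-room dwelling (29.04 / 23.54 / 21.78 m³)."""
    return pt.default_zone_system()


@pytest.fixture
def tracers3() -> tuple[pt.TracerSpec, ...]:
    """One tracer per room, four dosers each, 25 °C dosing rates."""
    return pt.default_tracers()


@pytest.fixture
def flows3() -> pt.FlowMatrix:
    """A seeded balanced 3-zone flow field."""
    return pt.generate_balanced_flows(3, (1.0, 100.0), seed=12345)


@pytest.fixture
def noiseless_measurement(zones3, tracers3, flows3) -> pt.SurveyMeasurement:
    conc = pt.steady_state_concentrations(flows3, list(tracers3))
    return pt.SurveyMeasurement(
        concentrations=conc, tracers=tracers3, zones=zones3
    )


def single_zone_flows(q: float = 50.0) -> pt.FlowMatrix:
    return pt.FlowMatrix(Q=np.array([[0.0, q], [q, 0.0]]))
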