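"""Shared fixtures.

The expensive simulations (steady pacing, both restitution protocols,
the 2D reentry run) are session-scoped and shared between the unit and
acceptance tests; everything runs at the default discretization
(dx = 0.25 mm, dt = 0.1 ms) unless a test needs otherwise.
"""

from __future__ import annotations

import numpy as np
import pytest

from epicard import ModelParameters
from epicard.protocols import diastolic_threshold
from epicard.validate import measure_cable_ap, measure_cell_ap


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def threshold_amplitude(params) -> float:
    """Tissue diastolic threshold on the default 2 cm cable (mV/s)."""
    return diastolic_threshold(params)


@pytest.fixture(scope="session")
def cable_steady(params, threshold_amplitude):
    """Mid-cable AP features and CV after ten 1 Hz beats at 2x threshold."""
    return measure_cable_ap(params, amplitude=2.0 * threshold_amplitude)


@pytest.fixture(scope="session")
def cell_ap(params):
    """Isolated-cell AP at twice the cell diastolic threshold."""
    return measure_cell_ap(params)


@pytest.fixture(scope="session")
def s1s2_curve(params, threshold_amplitude):
    from epicard.protocols import s1s2_restitution

    return s1s2_restitution(params, amplitude=2.0 * threshold_amplitude)


@pytest.fixture(scope="session")
def dynamic_result(params, threshold_amplitude):
    from epicard.protocols import dynamic_restitution

    return dynamic_restitution(params, amplitude=2.0 * threshold_amplitude)


@pytest.fixture(scope="session")
def spiral_result(params):
    """Full-resolution reentry run with late-window snapshots for tip
    tracking, plus its period statistics."""
    from epicard.spiral import initiate_spiral, period_statistics

    run = initiate_spiral(params, snapshot_cadence=5e-3,
                          snapshot_window=(3.4, 4.0))
    metrics = period_statistics(run)
    return run, metrics
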