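"""Shared fixtures.

The expensive Monte-Carlo artifacts (a calibrated-scene Brownian
trajectory, the calcium frequency sweep, the absorbing-cylinder
validation report) are session-scoped and shared between the unit tests
and the acceptance tests that examine different aspects of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from dendrocrowd.brownian import (
    SimConfig,
    make_calibrated_scene,
    run_linescan,
    validate_absorbing_cylinder,
)
from dendrocrowd.reduced import calibrate_geometry


@pytest.fixture(scope="session")
def calibrated_spec():
    """Compartment geometry calibrated to the twenty-fold slowdown."""
    return calibrate_geometry(0.05, 0.5, D=400.0)


@pytest.fixture(scope="session")
def calibrated_trajectory(calibrated_spec):
    """Brownian uncaging run in the calibrated barrier scene.

    2000 walkers for 50 ms (a scaled-down version of the full in-silico
    uncaging experiment; the acceptance script runs the full size).
    """
    scene = make_calibrated_scene(calibrated_spec, 20.0)
    cfg = SimConfig(D=400.0, n_particles=2000, rng_seed=9, sampling_period=0.7e-3)
    return run_linescan(
        scene, cfg, 0.05,
        axial_profile=lambda x: np.exp(-((x - 10.0) ** 2) / 2.0),
    )


@pytest.fixture(scope="session")
def frequency_sweep_result():
    """Spread-vs-frequency sweep with default (fill-flagged) parameters."""
    from dendrocrowd.calcium import frequency_sweep

    return frequency_sweep(t_end=1.0, overrides={"n_save": 41})


@pytest.fixture(scope="session")
def validation_report():
    """Absorbing-cylinder benchmark against the exact eigenseries."""
    return validate_absorbing_cylinder(
        SimConfig(D=400.0, n_particles=10_000, rng_seed=7)
    )
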