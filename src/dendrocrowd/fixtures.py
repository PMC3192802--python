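"""Synthetic uncaging line-scan fixtures.

Emulates the acquisition geometry of the photolysis experiments: a
Gaussian uncaging spot, line scans at a 0.7 ms period, read-out positions
at 0.6 μm steps from the spot center, several replicates averaged, and
additive Gaussian noise on the normalized signal.  The forward model is
the 1D reduced diffusion equation; the ground-truth diffusion constant is
recorded in a sidecar dict, never in the data file itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .linescan import LineScanRecord
from .reduced.pde1d import solve_reduced_1d


@dataclass(frozen=True)
class UncagingFixtureSpec:
    """Acquisition parameters of one synthetic uncaging experiment."""

    spot_center: float = 10.0  # μm
    spot_width: float = 1.0  # μm (Gaussian sigma of the uncaging spot)
    n_locations: int = 8  # read-out positions at 0.6 μm steps from center
    location_step: float = 0.6  # μm
    line_period: float = 0.7e-3  # s
    duration: float = 0.05  # s
    noise_sd: float = 0.03  # additive, on the normalized signal
    replicates: int = 10  # experimental band 7–14
    domain_length: float = 20.0  # μm
    dx: float = 0.05  # μm, forward-solver grid
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_width <= 0 or self.line_period <= 0 or self.duration <= 0:
            raise ValueError("spot width, line period and duration must be positive")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("invalid noise/replicate settings")
        if self.n_locations < 2:
            raise ValueError("need at least two read-out locations")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.line_period)) + 1
        return np.arange(n) * self.line_period

    @property
    def positions(self) -> np.ndarray:
        """Read-out positions: spot center plus multiples of the step."""
        return self.spot_center + np.arange(self.n_locations) * self.location_step


def generate_fixture(
    spec: UncagingFixtureSpec, truth_D: float
) -> tuple[LineScanRecord, dict]:
    """Forward-solve, sample on the line-scan grid, average noisy replicates.

    Returns the record and a truth sidecar (`truth_D`, resolved spec).
    With ``noise_sd=0`` and one replicate the record equals the solver
    output at the sample points exactly.
    """
    if truth_D <= 0:
        raise ValueError("truth_D must be positive")
    x = np.arange(0.0, spec.domain_length + spec.dx / 2, spec.dx)
    c0 = np.exp(-((x - spec.spot_center) ** 2) / (2.0 * spec.spot_width**2))
    sol = solve_reduced_1d(c0, x, spec.times, D=truth_D, bc="reflecting")
    # sample at the read-out positions
    clean = np.empty((spec.times.size, spec.positions.size))
    for i in range(spec.times.size):
        clean[i] = np.interp(spec.positions, x, sol.values[i])
    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd > 0:
        reps = clean[None, :, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.replicates, *clean.shape)
        )
        values = reps.mean(axis=0)
    else:
        values = clean.copy()
    meta = {
        "kind": "synthetic-uncaging-fixture",
        "line_period_s": spec.line_period,
        "location_step_um": spec.location_step,
        "replicates": spec.replicates,
        "noise_sd": spec.noise_sd,
        "rng_seed": spec.rng_seed,
    }
    record = LineScanRecord(spec.times, spec.positions, values, meta)
    sidecar = {"truth_D": truth_D, "spec": asdict(spec)}
    return record, sidecar
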