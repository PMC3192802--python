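"""Self-validation of the Brownian engine against exact eigenfunction series.

A bare cylinder with absorbing top and bottom caps and reflecting lateral
wall reduces exactly to 1D diffusion on [0, L] with absorbing ends.  For a
uniform initial condition the survival fraction is

    S(t) = Σ_{n odd} (8 / n²π²) · exp(−n²π² D t / L²),

and the local concentration (relative to the initial uniform value) is

    c(x, t)/c₀ = Σ_{n odd} (4 / nπ) · sin(nπx/L) · exp(−n²π² D t / L²).

The report compares simulated curves against the truncated series and the
mean first passage time against its closed form ⟨τ⟩ = L²/(12 D) for a
uniform start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import run_linescan
from .estimators import record_linescan
from .scene import SamplingVolume, Scene, SimConfig


def survival_series(t, D: float, L: float, n_terms: int = 101) -> np.ndarray:
    """Truncated eigenseries for the surviving fraction (≥50 odd terms)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    lam = (n * np.pi / L) ** 2 * D
    out = (8.0 / (n * np.pi) ** 2)[None, :] * np.exp(-lam[None, :] * t[:, None])
    return out.sum(axis=1)


def local_concentration_series(
    x, t, D: float, L: float, n_terms: int = 101, bin_height: float = 0.0
):
    """c(x,t)/c0 for uniform initial condition and absorbing ends.

    With ``bin_height`` > 0 the series is averaged over the sampling
    volume [x − h/2, x + h/2], matching what a counting detector sees.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    lam = (n * np.pi / L) ** 2 * D
    k = n * np.pi / L
    if bin_height > 0:
        h = bin_height
        spatial = (np.cos(k * (x - h / 2)) - np.cos(k * (x + h / 2))) / (k * h)
    else:
        spatial = np.sin(k * x)
    modes = (4.0 / (n * np.pi))[None, :] * spatial[None, :]
    return (modes * np.exp(-lam[None, :] * t[:, None])).sum(axis=1)


@dataclass
class ValidationReport:
    survival_sup_error: float
    local_sup_error: float
    mfpt_sim: float
    mfpt_exact: float
    passed: bool
    details: dict = field(default_factory=dict)


def validate_absorbing_cylinder(
    config: SimConfig | None = None,
    radius: float = 0.5,
    length: float = 5.0,
    duration: float | None = None,
    survival_tol: float = 0.02,
    local_tol: float = 0.12,
    mfpt_tol: float = 0.05,
) -> ValidationReport:
    """Run the absorbing-cylinder benchmark and compare with exact series.

    Checks (i) the global survival fraction, (ii) the normalized local
    concentration in a mid-cylinder sampling volume and (iii) the mean
    first passage time to the caps (uniform start: L²/(12D)).

    The local tolerance is dominated by counting noise: the central
    volume holds ~10% of the walkers, so each frame carries ~3% relative
    binomial noise and the sup over ~50 frames reaches ~3σ ≈ 0.1.
    """
    if config is None:
        config = SimConfig(D=400.0, n_particles=10_000, rng_seed=7)
    D, L = config.D, length
    if duration is None:
        # several fundamental relaxation times, so nearly all walkers escape
        duration = 6.0 * L * L / (np.pi**2 * D)
    scene = Scene(
        cylinder_radius=radius,
        cylinder_length=length,
        end_conditions=("absorbing", "absorbing"),
    )
    traj = run_linescan(scene, config, duration)

    # global survival
    surv_sim = traj.active.sum(axis=1) / config.n_particles
    surv_exact = survival_series(traj.times, D, L)
    sup_err = float(np.max(np.abs(surv_sim - surv_exact)))

    # local concentration in a central sampling volume
    h = 0.5
    rec = record_linescan(
        traj, [SamplingVolume(center_x=L / 2, height=h)], normalize=False
    )
    c_sim = rec.raw_counts[:, 0] / rec.raw_counts[0, 0]
    c_exact = local_concentration_series(L / 2, traj.times, D, L, bin_height=h)
    c_exact = c_exact / c_exact[0]
    loc_err = float(np.max(np.abs(c_sim - c_exact)))

    # MFPT to the caps
    abs_t = traj.ensemble.absorption_times
    esc = abs_t[np.isfinite(abs_t)]
    mfpt_sim = float(esc.mean()) if esc.size else float("nan")
    mfpt_exact = L * L / (12.0 * D)
    mfpt_ok = (
        esc.size > 0.99 * config.n_particles
        and abs(mfpt_sim - mfpt_exact) / mfpt_exact < mfpt_tol
    )

    passed = sup_err <= survival_tol and loc_err <= local_tol and bool(mfpt_ok)
    return ValidationReport(
        survival_sup_error=sup_err,
        local_sup_error=loc_err,
        mfpt_sim=mfpt_sim,
        mfpt_exact=mfpt_exact,
        passed=passed,
        details={
            "n_particles": config.n_particles,
            "duration_s": duration,
            "survival_tol": survival_tol,
            "local_tol": local_tol,
            "mfpt_tol": mfpt_tol,
            "escaped_fraction": esc.size / config.n_particles,
        },
    )
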