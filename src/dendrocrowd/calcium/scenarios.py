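"""Named calcium-dynamics scenarios and the frequency sweep.

The scenario family contrasts aqueous (D = 400 μm²/s) against crowded
(D = 20 μm²/s) diffusion, bare against buffered-and-pumped dendrites, and
adds sustained NMDA-receptor input at the midpoint of a 20 μm segment:

=================  ==========================================================
``fig4a``          pulse in aqueous solution, bare diffusion
``fig4b``          pulse in the crowded dendrite, bare diffusion
``fig4c``          aqueous + medium buffers (CaM 25 μM, CN 10 μM) + pumps
``fig4d``          crowded + medium buffers + pumps
``fig4e``          1 s NMDA pulse train at the midpoint, crowded, buffered
``frequency_sweep``  fig4e repeated over input frequencies
=================  ==========================================================
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .solver import assemble_and_solve
from .specs import (
    CALCINEURIN,
    CALMODULIN,
    FLUO4,
    NCX,
    PMCA,
    ReactionSystemSpec,
    SynapseSpec,
)
from .spread import measure_spread

#: default initial uncaging-like pulse: peak concentration (μM) and
#: Gaussian width (μm); the peak is a literature fill (≈600 particles/μm³)
PULSE_PEAK_UM = 1.0
PULSE_SIGMA_UM = 0.5

D_AQUEOUS = 400.0
D_CROWDED = 20.0

SCENARIOS = ("fig4a", "fig4b", "fig4c", "fig4d", "fig4e", "frequency_sweep")


def _gaussian_pulse(center: float, peak: float = PULSE_PEAK_UM, sigma: float = PULSE_SIGMA_UM):
    def profile(x: float) -> float:
        return peak * math.exp(-((x - center) ** 2) / (2.0 * sigma**2))

    return profile


def _base_system(D: float, buffered: bool, **overrides) -> ReactionSystemSpec:
    kwargs = dict(
        length=20.0,
        dendrite_radius=0.5,
        D_ca=D,
        dx=0.05,
        buffers=(CALMODULIN, CALCINEURIN) if buffered else (),
        dye=FLUO4 if buffered else None,
        pumps=(PMCA, NCX) if buffered else (),
        synapse=None,
        spines=None,
    )
    kwargs.update(overrides)
    return ReactionSystemSpec(**kwargs)


def _synapse(frequency: float, duration: float, position: float) -> SynapseSpec:
    n_pulses = int(round(frequency * duration))
    if n_pulses < 1:
        raise ValueError(
            f"frequency {frequency} Hz over {duration} s yields no pulses"
        )
    return SynapseSpec(position=position, frequency=frequency, n_pulses=n_pulses)


def run_scenario(name: str, overrides: dict | None = None):
    """Run one named scenario; returns (trajectory, report).

    ``overrides`` may contain any :class:`ReactionSystemSpec` field, plus
    ``t_end``, ``n_save``, ``frequency`` (for ``fig4e``) and
    ``frequencies`` (for ``frequency_sweep``).
    """
    overrides = dict(overrides or {})
    t_end = overrides.pop("t_end", None)
    n_save = overrides.pop("n_save", 81)
    frequency = overrides.pop("frequency", 20.0)
    frequencies = overrides.pop("frequencies", (1.0, 5.0, 10.0, 20.0, 50.0, 100.0))

    if name == "frequency_sweep":
        return frequency_sweep(
            frequencies=frequencies,
            t_end=t_end or 1.0,
            overrides=overrides,
        )

    if name in ("fig4a", "fig4b", "fig4c", "fig4d"):
        D = D_AQUEOUS if name in ("fig4a", "fig4c") else D_CROWDED
        buffered = name in ("fig4c", "fig4d")
        system = _base_system(D, buffered, **overrides)
        t_end = t_end or 0.01
        pulse = _gaussian_pulse(system.length / 2.0)
        traj = assemble_and_solve(system, t_end, ca_profile=pulse, n_save=n_save)
    elif name == "fig4e":
        system = _base_system(D_CROWDED, True, **overrides)
        t_end = t_end or 1.0
        syn = _synapse(frequency, t_end, system.length / 2.0)
        system = replace(system, synapse=syn)
        traj = assemble_and_solve(system, t_end, n_save=n_save)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")

    spread = measure_spread(traj)
    report = {
        "scenario": name,
        "t_end_s": t_end,
        "parameters": traj.system.resolved_parameters(),
        "max_spread_um": float(np.nanmax(spread["spread"])),
        "peak_ca_uM": float(traj.free_ca_concentration().max()),
        "budget": {
            k: (float(v[-1]) if np.ndim(v) else float(v))
            for k, v in traj.budget().items()
            if k != "relative_closure_error"
        },
        "max_budget_closure_error": float(traj.budget()["relative_closure_error"].max()),
    }
    return traj, report


def saturation_frequency(freqs: np.ndarray, spreads: np.ndarray, rel_tol: float = 0.10) -> float:
    """Smallest tested frequency beyond which the spread is stationary.

    Stationary means every further consecutive frequency increase changes
    the spread by at most ``rel_tol`` relative.
    """
    freqs = np.asarray(freqs, dtype=float)
    spreads = np.asarray(spreads, dtype=float)
    order = np.argsort(freqs)
    f, s = freqs[order], spreads[order]
    rel = np.abs(np.diff(s)) / np.maximum(s[:-1], 1e-300)
    for i in range(f.size - 1):
        if np.all(rel[i:] <= rel_tol):
            return float(f[i])
    return float(f[-1])


def frequency_sweep(
    frequencies=(1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    t_end: float = 1.0,
    overrides: dict | None = None,
):
    """NMDA input at the segment midpoint over a range of frequencies.

    Returns (per-frequency trajectories, report); the report contains a
    tidy spread table, the maximum spread at and above 20 Hz, and the
    saturation frequency.
    """
    overrides = dict(overrides or {})
    n_save = overrides.pop("n_save", 81)
    rows = []
    trajectories = {}
    for f in frequencies:
        system = _base_system(D_CROWDED, True, **overrides)
        syn = _synapse(f, t_end, system.length / 2.0)
        system = replace(system, synapse=syn)
        traj = assemble_and_solve(system, t_end, n_save=n_save)
        sp = measure_spread(traj)
        trajectories[f] = traj
        rows.append(
            {
                "frequency_hz": f,
                "max_spread_um": float(np.nanmax(sp["spread"])),
                "max_fwhm_um": float(np.nanmax(sp["fwhm"])),
                "peak_ca_uM": float(traj.free_ca_concentration().max()),
                "budget_closure_error": float(
                    traj.budget()["relative_closure_error"].max()
                ),
            }
        )
    table = pd.DataFrame(rows)
    freqs = table["frequency_hz"].to_numpy()
    spreads = table["max_spread_um"].to_numpy()
    high = freqs >= 20.0
    report = {
        "scenario": "frequency_sweep",
        "t_end_s": t_end,
        "parameters": next(iter(trajectories.values())).system.resolved_parameters(),
        "table": table,
        "max_spread_high_freq_um": float(spreads[high].max()) if high.any() else float("nan"),
        "saturation_frequency_hz": saturation_frequency(freqs, spreads),
    }
    return trajectories, report
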