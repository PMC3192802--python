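"""Reaction terms of the calcium system: buffers, pumps, spines, synapses.

All terms act on particle-per-length densities; bimolecular rate constants
are tabulated in concentration units (1/(μM·s)) and the free-calcium
density is converted to μM through the dendritic cross-section where it
enters a product.
"""

from __future__ import annotations

import numpy as np

from ..reduced.narrow_escape import mfpt_escape_3d
from ..units import current_to_ion_rate, linear_density_to_concentration
from .specs import BufferSpec, PumpSpec, SynapseSpec


def buffer_rhs(u_ca, u_buffer, spec: BufferSpec, cross_section: float):
    """Mass-action derivatives for the sequential binding ladder.

    Parameters
    ----------
    u_ca
        Free-calcium density, particles/μm (scalar or grid array).
    u_buffer
        Occupancy-state densities, shape ``(n_sites+1, ...)``: row j holds
        the buffer carrying j bound calcium ions.
    Returns
    -------
    (du_ca, du_buffer)
        Time derivatives; the occupancy rows sum to zero identically, so
        total buffer is conserved by construction, and du_ca equals minus
        the net calcium bound.
    """
    u_ca = np.asarray(u_ca, dtype=float)
    u_b = np.asarray(u_buffer, dtype=float)
    n = spec.n_sites
    if u_b.shape[0] != n + 1:
        raise ValueError(f"expected {n + 1} occupancy states, got {u_b.shape[0]}")
    c_ca = linear_density_to_concentration(u_ca, cross_section)  # μM
    du_b = np.zeros_like(u_b)
    du_ca = np.zeros_like(u_ca)
    for j in range(1, n + 1):
        forward = spec.k_forward[j - 1] * c_ca * u_b[j - 1]  # particles/(μm s)
        backward = spec.k_backward[j - 1] * u_b[j]
        net = forward - backward
        du_b[j - 1] -= net
        du_b[j] += net
        du_ca -= net
    return du_ca, du_b


def buffer_equilibrium(spec: BufferSpec, c_ca: float) -> np.ndarray:
    """Equilibrium occupancy fractions of the ladder at clamped [Ca] (μM).

    Detailed balance gives p_j ∝ Π_{i≤j} (k_f,i · c / k_b,i); for equal
    site pairs this reduces to a binomial distribution in j.
    """
    if c_ca < 0:
        raise ValueError("concentration must be non-negative")
    w = [1.0]
    for j in range(spec.n_sites):
        w.append(w[-1] * spec.k_forward[j] * c_ca / spec.k_backward[j])
    w = np.asarray(w)
    return w / w.sum()


def pump_flux(
    u_ca_node,
    pump: PumpSpec,
    perimeter: float,
    cross_section: float,
):
    """Calcium loss through a membrane pump, particles/(μm·s) (≥ 0).

    Hill activation ``c^h/(K^h + c^h)`` of the per-pump extrusion rate,
    times the pump surface density and the membrane perimeter.  Saturates
    at rate·density·perimeter for c ≫ K and is half-maximal at c = K.
    """
    u = np.asarray(u_ca_node, dtype=float)
    if np.any(u < 0):
        u = np.clip(u, 0.0, None)
    c = linear_density_to_concentration(u, cross_section)
    activation = c**pump.hill / (pump.K_half**pump.hill + c**pump.hill + 1e-300)
    return pump.rate_per_pump * pump.surface_density * perimeter * activation


def spine_sink_rate(
    neck_radius: float,
    compartment_volume: float,
    D: float,
    dendrite_radius: float | None = None,
) -> float:
    """Per-spine absorption rate 1/τ = 4·D·r_neck / V  (1/s).

    The inverse of the narrow-escape time to find the spine-neck opening
    from within one compartment volume.
    """
    if dendrite_radius is not None and neck_radius >= dendrite_radius:
        raise ValueError(
            f"neck radius {neck_radius} must be smaller than the dendrite "
            f"radius {dendrite_radius}"
        )
    return 1.0 / mfpt_escape_3d(compartment_volume, neck_radius, D)


def footprint_weights(x_grid: np.ndarray, dx: float, center: float, half_width: float):
    """Overlap fractions of a rectangle [c−w, c+w] with each grid cell.

    Cells are [x−dx/2, x+dx/2]; the weights sum to 1, so a source using
    them injects its particle budget exactly regardless of grid alignment.
    """
    lo = np.maximum(x_grid - 0.5 * dx, center - half_width)
    hi = np.minimum(x_grid + 0.5 * dx, center + half_width)
    w = np.clip(hi - lo, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("source footprint does not overlap the grid")
    return w / total


def nmda_current(t, spec: SynapseSpec):
    """Summed NMDA pulse-train current (pA) at time(s) t.

    Each pulse is the difference of two exponentials normalized so its
    peak equals ``peak_current``; pulse onsets are t0 + i/frequency for
    i = 0…n_pulses−1, and the current is zero before t0.  With
    ``saturating`` (default) the summed train is clipped at
    ``peak_current``: the single receptor cannot exceed its open-channel
    current, so the mean influx saturates once pulses overlap strongly
    (frequencies above ~1/τ_decay).
    """
    t = np.asarray(t, dtype=float)
    tr, td = spec.tau_rise, spec.tau_decay
    ttp = spec.time_to_peak
    gmax = np.exp(-ttp / td) - np.exp(-ttp / tr)
    out = np.zeros_like(t, dtype=float)
    for i in range(spec.n_pulses):
        ti = spec.t0 + i / spec.frequency
        dt = t - ti
        on = dt > 0
        out = out + np.where(on, np.exp(-np.clip(dt, 0, None) / td) - np.exp(-np.clip(dt, 0, None) / tr), 0.0)
    current = spec.peak_current / gmax * out
    if spec.saturating:
        current = np.minimum(current, spec.peak_current)
    return current


def nmda_particle_flux(t, spec: SynapseSpec, x_grid, dx: float | None = None):
    """Calcium source density, particles/(μm·s), on the grid at time t.

    The electrical current converts to an ion rate I·f_Ca/(2e) and is
    deposited on a rectangular footprint of half-width ``receptor_radius``
    centered at the receptor position.
    """
    x = np.asarray(x_grid, dtype=float)
    if dx is None:
        dx = float(x[1] - x[0]) if x.size > 1 else 2 * spec.receptor_radius
    ions_per_s = current_to_ion_rate(float(nmda_current(t, spec)), spec.ca_fraction)
    w = footprint_weights(x, dx, spec.position, spec.receptor_radius)
    return ions_per_s * w / dx
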