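"""Unit conventions and the conversion factors used throughout the package.

All lengths are micrometres (μm), times seconds (s), diffusion constants
μm²/s, concentrations micromolar (μM) and linear densities particles/μm.
Every physical constant and conversion factor lives here so that no other
module hard-codes one.
"""

from __future__ import annotations

import math

#: particles per μm³ corresponding to a 1 μM concentration
#: (1 μM = 1e-6 mol/L = 6.02214e17 / L = 602.214 / μm³).
PARTICLES_PER_UM3_PER_UM = 602.214

#: elementary charge in coulomb
ELEMENTARY_CHARGE = 1.602176634e-19

#: valence of the calcium ion
CALCIUM_VALENCE = 2


def cross_section_area(radius_um: float) -> float:
    """Cross-sectional area π a² of a cylindrical dendrite, in μm²."""
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    return math.pi * radius_um**2


def concentration_to_linear_density(c_um: float, cross_section_um2: float) -> float:
    """Convert a concentration (μM) to particles per unit dendrite length.

    A volumetric density of ``602.214 * c`` particles/μm³ occupying a
    cylinder of cross-section ``S`` gives ``602.214 * c * S`` particles/μm;
    e.g. 1 μM (≈600 particles/μm³) in a 1 μm diameter dendrite
    (S = 0.785 μm²) is ≈470 particles/μm.
    """
    import numpy as np

    if np.any(np.asarray(c_um) < 0):
        raise ValueError("concentration must be non-negative")
    if cross_section_um2 <= 0:
        raise ValueError("cross-section must be positive")
    return c_um * PARTICLES_PER_UM3_PER_UM * cross_section_um2


def linear_density_to_concentration(u_per_um, cross_section_um2: float):
    """Inverse of :func:`concentration_to_linear_density` (μM from particles/μm)."""
    if cross_section_um2 <= 0:
        raise ValueError("cross-section must be positive")
    return u_per_um / (PARTICLES_PER_UM3_PER_UM * cross_section_um2)


def current_to_ion_rate(current_pa: float, ca_fraction: float) -> float:
    """Calcium ions per second carried by a membrane current.

    ``ions/s = I * f_Ca / (z e)`` with valence z = 2; the current is given
    in pA (1 pA = 1e-12 C/s).
    """
    return current_pa * 1e-12 * ca_fraction / (CALCIUM_VALENCE * ELEMENTARY_CHARGE)


def ms_to_s(t_ms: float) -> float:
    return t_ms * 1e-3


def s_to_ms(t_s: float) -> float:
    return t_s * 1e3
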