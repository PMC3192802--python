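"""Mean time for a particle to travel along a dendrite under the reduced model.

Standard first-passage theory applied to the effective 1D equation.  For
constant coefficients with an absorbing soma at x = 0 and a sealed
(reflecting) distal end at x = L_dend:

    τ_to_soma(x) = (2 L_dend x − x²) / (2 D_eff),

so a molecule starting at the tip of a 100 μm dendrite with
D_eff = 20 μm²/s needs 250 s (≈ 4 min) to reach the soma.  For general
ε(x), V(x) the MFPT is obtained by double quadrature of the reduced
generator.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .geometry import CompartmentSpec, InhomogeneousProfile


def _check_position(x: float, L_dend: float) -> None:
    if not 0 <= x <= L_dend:
        raise ValueError(f"position x={x} outside the dendrite [0, {L_dend}]")
    if L_dend <= 0:
        raise ValueError(f"dendrite length must be positive, got {L_dend}")


def mfpt_to_soma(x: float, L_dend: float, D_eff: float) -> float:
    """Mean time (s) to reach the absorbing soma at 0 from position x.

    The distal end at ``L_dend`` is reflecting.  Zero at x = 0, monotone
    increasing and quadratic in x.
    """
    _check_position(x, L_dend)
    if D_eff <= 0:
        raise ValueError(f"D_eff must be positive, got {D_eff}")
    return (2.0 * L_dend * x - x * x) / (2.0 * D_eff)


def mfpt_from_soma(x: float, L_dend: float, D_eff: float) -> float:
    """Mean time (s) to reach an absorbing site at ``L_dend`` starting from
    position x, with the soma end at 0 reflecting.

    Mirror-symmetric partner of :func:`mfpt_to_soma`:
    ``mfpt_from_soma(L_dend − x) == mfpt_to_soma(x)``.
    """
    _check_position(x, L_dend)
    if D_eff <= 0:
        raise ValueError(f"D_eff must be positive, got {D_eff}")
    return (L_dend * L_dend - x * x) / (2.0 * D_eff)


def mfpt_to_soma_general(
    x: float,
    profile: InhomogeneousProfile,
    spec: CompartmentSpec,
    L_dend: float | None = None,
) -> float:
    """MFPT to the absorbing soma for spatially varying ε(x), V(x).

    Double quadrature of the reduced generator b T″ + a T′ = −1 with
    T(0) = 0 and T′(L_dend) = 0, where a = 2DL²ε′/V and b = 2DL²ε/V:

        T(x) = ∫₀ˣ dy / ε(y) · ∫_y^{L} V(z) dz / (2 D L²).

    Reduces to :func:`mfpt_to_soma` for constant ε and V.
    """
    if L_dend is None:
        L_dend = profile.domain[1]
    _check_position(x, L_dend)
    pref = 2.0 * spec.D * spec.L**2

    def inner(y: float) -> float:
        val, _ = quad(profile.V_of_x, y, L_dend, limit=200)
        return val / (pref * profile.eps_of_x(y))

    val, _ = quad(inner, 0.0, x, limit=200)
    return val
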