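"""Conservative finite-volume solver for the reduced 1D diffusion equation.

Homogeneous compartments give the plain effective diffusion equation

    ∂c/∂t = D_eff ∂²c/∂x²,        D_eff = (2εL/S)·D.

With spatially varying opening radius ε(x) and compartment volume V(x) the
reduction instead reads

    ∂(V c)/∂t = 2 D L² ∂/∂x ( ε(x) ∂c/∂x ),

which is discretized in flux-conservative form so that mass is conserved
to solver precision under reflecting boundaries.  The associated Itô
process has drift a(x) = 2DL² ε′(x)/V(x) and diffusion
b(x) = 2DL² ε(x)/V(x); the drift disappears for spatially homogeneous
opening sizes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import factorized

from ..linescan import LineScanRecord
from .geometry import CompartmentSpec, InhomogeneousProfile, effective_diffusion_constant

_BCS = ("reflecting", "absorbing", "mixed")


def drift_and_diffusion_coefficients(
    profile: InhomogeneousProfile, spec: CompartmentSpec
):
    """Drift a(x) (μm/s) and diffusion b(x) (μm²/s) of the reduced SDE.

    Returns a pair of vectorized callables.  In the homogeneous limit
    b(x) ≡ D_eff and a(x) ≡ 0.
    """
    pref = 2.0 * spec.D * spec.L**2

    eps_f = np.vectorize(profile.eps_of_x)
    vol_f = np.vectorize(profile.V_of_x)

    def b_of_x(x):
        return pref * eps_f(x) / vol_f(x)

    def a_of_x(x):
        return pref * profile.deps_dx(x) / vol_f(x)

    return a_of_x, b_of_x


def _face_coefficients(x, spec, profile, D):
    """Diffusive conductance on cell faces and cell 'volume' weights."""
    nx = x.size
    if profile is not None:
        if spec is None:
            raise ValueError("an inhomogeneous profile requires a CompartmentSpec")
        pref = 2.0 * spec.D * spec.L**2
        xf = 0.5 * (x[:-1] + x[1:])
        eps_face = np.asarray([profile.eps_of_x(xi) for xi in xf], dtype=float)
        cond = pref * eps_face  # multiplies (c_{i+1}-c_i)/dx
        vol = np.asarray([profile.V_of_x(xi) for xi in x], dtype=float)
    else:
        if D is None:
            D = effective_diffusion_constant(spec)
        cond = np.full(nx - 1, float(D))
        vol = np.ones(nx)
    return cond, vol


def solve_reduced_1d(
    c0,
    x_grid,
    t_grid,
    spec: CompartmentSpec | None = None,
    D: float | None = None,
    profile: InhomogeneousProfile | None = None,
    bc: str = "reflecting",
) -> LineScanRecord:
    """Evolve an initial concentration profile under the reduced equation.

    Parameters
    ----------
    c0
        Initial concentration on ``x_grid`` (≥ 0).
    x_grid, t_grid
        Uniform spatial grid (μm) and output times (s, starting at 0).
    spec, D, profile
        Either a bare diffusion constant ``D``, a :class:`CompartmentSpec`
        (its D_eff is used), or an :class:`InhomogeneousProfile` together
        with a spec for the prefactor 4DL².
    bc
        ``reflecting`` | ``absorbing`` | ``mixed`` (absorbing at x=0,
        reflecting at the far end).

    Returns
    -------
    LineScanRecord
        Concentration matrix of shape (nt, nx); Crank–Nicolson in time.
    """
    x = np.asarray(x_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0):
        raise ValueError("initial concentration must be non-negative")
    if c0.shape != x.shape:
        raise ValueError("c0 and x_grid shapes differ")
    if bc not in _BCS:
        raise ValueError(f"bc must be one of {_BCS}, got {bc!r}")
    dx = float(x[1] - x[0])
    if not np.allclose(np.diff(x), dx, rtol=1e-10):
        raise ValueError("x_grid must be uniform")

    nx = x.size
    cond, vol = _face_coefficients(x, spec, profile, D)

    # assemble the FV operator  dc/dt = A c
    w = cond / dx**2
    lower = np.zeros(nx)
    upper = np.zeros(nx)
    main = np.zeros(nx)
    lower[1:] = w / vol[1:]
    upper[:-1] = w / vol[:-1]
    main[:-1] -= w / vol[:-1]
    main[1:] -= w / vol[1:]

    absorbing_left = bc in ("absorbing", "mixed")
    absorbing_right = bc == "absorbing"
    A = sp.diags_array(
        (lower[1:], main, upper[:-1]), offsets=(-1, 0, 1), format="csr"
    ).tolil()
    for idx, on in ((0, absorbing_left), (nx - 1, absorbing_right)):
        if on:
            A[idx, :] = 0.0  # Dirichlet c = 0
    A = A.tocsc()

    # Crank–Nicolson with a fixed internal step small enough for accuracy
    d_scale = float(np.max(cond / vol[:-1])) if nx > 1 else 1.0
    dt_target = 0.25 * dx**2 / max(d_scale, 1e-30)

    values = np.empty((t.size, nx))
    c = c0.copy()
    if absorbing_left:
        c[0] = 0.0
    if absorbing_right:
        c[-1] = 0.0
    values[0] = c
    eye = sp.identity(nx, format="csc")

    for k in range(1, t.size):
        span = t[k] - t[k - 1]
        n_sub = max(1, int(np.ceil(span / dt_target)))
        n_sub = min(n_sub, 20000)
        dt = span / n_sub
        lhs = factorized((eye - 0.5 * dt * A).tocsc())
        rhs_op = eye + 0.5 * dt * A
        for _ in range(n_sub):
            c = lhs(rhs_op @ c)
        values[k] = c

    meta = {
        "bc": bc,
        "dx_um": dx,
        "solver": "crank-nicolson-fv",
    }
    return LineScanRecord(t, x, values, meta)
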