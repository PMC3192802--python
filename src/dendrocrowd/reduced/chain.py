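"""Compartment-chain master equation for particle numbers N_j(t).

Mass conservation across the small openings gives, with the aperture hop
rate k = 2Dε/V between neighboring compartments,

    dN_j/dt = k (N_{j-1} − 2 N_j + N_{j+1}),

with reflecting (no flux) or absorbing (N ≡ 0 outside) end conditions.
In the continuum limit this chain converges to the effective 1D diffusion
equation with D_eff = k L².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class CompartmentChainState:
    """Particle counts per compartment at one time point."""

    counts: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class ChainTrajectory:
    """Solution of the chain ODEs on a time grid: counts has shape (nt, M)."""

    times: np.ndarray
    counts: np.ndarray
    spec: "object"
    bc: str

    def state_at(self, i: int) -> CompartmentChainState:
        return CompartmentChainState(np.clip(self.counts[i], 0.0, None), self.times[i])

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def positions(self) -> np.ndarray:
        """Compartment centers, origin at the left end of the chain."""
        M = self.counts.shape[1]
        return (np.arange(M) + 0.5) * self.spec.L


def solve_compartment_chain(
    state0: CompartmentChainState,
    spec,
    t_end: float,
    n_save: int = 50,
    bc: str = "reflecting",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ChainTrajectory:
    """Integrate the compartment-chain ODEs from ``state0`` to ``t_end``.

    Parameters
    ----------
    state0
        Initial counts; at least 3 compartments.
    spec
        :class:`~dendrocrowd.reduced.geometry.CompartmentSpec`; supplies the
        hop rate 1/τ = 4Dε/V.
    bc
        ``"reflecting"`` (total count conserved) or ``"absorbing"``
        (particles leaving the end compartments are lost).
    """
    M = state0.counts.size
    if M < 3:
        raise ValueError(f"need at least 3 compartments, got {M}")
    if bc not in ("reflecting", "absorbing"):
        raise ValueError(f"unknown boundary condition {bc!r}")

    k = 1.0 / spec.hop_time  # hop rate per direction, 1/s

    # tridiagonal Laplacian of the chain
    main = np.full(M, -2.0 * k)
    if bc == "reflecting":
        main[0] = main[-1] = -k
    off = np.full(M - 1, k)

    def rhs(t, y):
        dy = main * y
        dy[:-1] += off * y[1:]
        dy[1:] += off * y[:-1]
        return dy

    t_eval = np.linspace(0.0, t_end, n_save)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        state0.counts,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        lband=1,
        uband=1,
    )
    if not sol.success:  # pragma: no cover - solver diagnostics passthrough
        raise RuntimeError(f"chain solver failed: {sol.message}")
    return ChainTrajectory(sol.t, sol.y.T, spec, bc)
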