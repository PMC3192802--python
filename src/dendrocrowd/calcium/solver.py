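"""Method-of-lines solver for the coupled calcium reaction-diffusion system.

Free calcium (particles/μm) diffuses on a uniform grid with reflecting
ends and exchanges with immobile buffer occupancy states, a single-site
dye, Hill-activated membrane pumps, passive spine sinks and an NMDA
source.  The stiff ODE system is integrated with BDF and an analytically
assembled sparse Jacobian; cumulative pump, spine and injection fluxes are
carried as quadrature states so the calcium budget can be audited exactly
at solver accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from ..units import (
    PARTICLES_PER_UM3_PER_UM,
    concentration_to_linear_density,
)
from .kinetics import footprint_weights, nmda_current, spine_sink_rate
from .specs import ReactionSystemSpec
from ..units import current_to_ion_rate


@dataclass
class CalciumState:
    """Densities of free Ca, buffer occupancy states and bound dye at time t."""

    grid: np.ndarray
    u_ca: np.ndarray
    u_buffer: dict
    u_dye: np.ndarray | None
    t: float


@dataclass
class CalciumTrajectory:
    """Full solution: raw state matrix plus layout metadata and audits."""

    times: np.ndarray
    raw: np.ndarray  # (nt, n_state)
    grid: np.ndarray
    system: ReactionSystemSpec
    layout: dict = field(repr=False, default_factory=dict)

    def free_ca(self) -> np.ndarray:
        """Free-calcium density (nt, nx), particles/μm."""
        return np.clip(self.raw[:, self.layout["ca"]], 0.0, None)

    def free_ca_concentration(self) -> np.ndarray:
        """Free calcium in μM."""
        return self.free_ca() / (PARTICLES_PER_UM3_PER_UM * self.system.cross_section)

    def buffer_states(self, name: str) -> np.ndarray:
        """Occupancy densities (nt, n_sites+1, nx) for one buffer."""
        sl, n_states = self.layout["buffers"][name]
        nx = self.grid.size
        return self.raw[:, sl].reshape(self.times.size, n_states, nx)

    def bound_dye(self) -> np.ndarray | None:
        sl = self.layout.get("dye")
        return None if sl is None else np.clip(self.raw[:, sl], 0.0, None)

    def bound_calcium(self) -> np.ndarray:
        """Calcium held by buffers and dye (nt, nx)."""
        out = np.zeros((self.times.size, self.grid.size))
        for name, (sl, n_states) in self.layout["buffers"].items():
            states = self.buffer_states(name)
            occupancy = np.arange(n_states)[None, :, None]
            out += (states * occupancy).sum(axis=1)
        if self.layout.get("dye") is not None:
            out += self.bound_dye()
        return out

    def cumulative(self, which: str) -> np.ndarray:
        """Quadrature state: 'pumped' | 'spines' | 'injected' (particles)."""
        return self.raw[:, self.layout["accumulators"][which]]

    def budget(self) -> dict:
        """Calcium budget audit at every output time.

        closure[t] = (free + bound + pumped + spine-absorbed − injected)
                     − initial total, relative to the running total.
        """
        dx = self.system.dx
        free = self.free_ca().sum(axis=1) * dx
        bound = self.bound_calcium().sum(axis=1) * dx
        pumped = self.cumulative("pumped")
        spined = self.cumulative("spines")
        injected = self.cumulative("injected")
        total0 = free[0] + bound[0]
        balance = free + bound + pumped + spined - injected
        scale = np.maximum(np.maximum(free + bound, injected), total0) + 1e-300
        return {
            "free": free,
            "bound": bound,
            "pumped": pumped,
            "spines": spined,
            "injected": injected,
            "initial_total": total0,
            "relative_closure_error": np.abs(balance - total0) / scale,
        }

    def state_at(self, i: int) -> CalciumState:
        buffers = {
            name: self.buffer_states(name)[i]
            for name in self.layout["buffers"]
        }
        dye = self.bound_dye()
        return CalciumState(
            grid=self.grid,
            u_ca=self.free_ca()[i],
            u_buffer=buffers,
            u_dye=None if dye is None else dye[i],
            t=float(self.times[i]),
        )


def _build_layout(system: ReactionSystemSpec, nx: int):
    """Slices into the flat state vector, species-block ordered."""
    layout = {"ca": slice(0, nx), "buffers": {}, "blocks": {"ca": 0}}
    pos = nx
    block = 1
    for buf in system.buffers:
        n_states = buf.n_sites + 1
        layout["buffers"][buf.name] = (slice(pos, pos + n_states * nx), n_states)
        layout["blocks"][buf.name] = block
        pos += n_states * nx
        block += n_states
    if system.dye is not None:
        layout["dye"] = slice(pos, pos + nx)
        layout["blocks"]["dye"] = block
        pos += nx
        block += 1
    else:
        layout["dye"] = None
    layout["n_blocks"] = block
    layout["accumulators"] = {
        "pumped": pos,
        "spines": pos + 1,
        "injected": pos + 2,
    }
    layout["n_state"] = pos + 3
    return layout


class _Assembler:
    """Vectorized RHS and analytic sparse Jacobian of the full system."""

    def __init__(self, system: ReactionSystemSpec, grid: np.ndarray, layout: dict):
        self.sys = system
        self.x = grid
        self.nx = grid.size
        self.layout = layout
        self.gamma = 1.0 / (PARTICLES_PER_UM3_PER_UM * system.cross_section)
        self.dx = system.dx
        # spine sink rate profile k(x) (1/s)
        k_sp = np.zeros(self.nx)
        if system.spines is not None:
            spine = system.spines
            # the escape volume is one crowding compartment around the neck
            v_comp = system.cross_section * spine.compartment_length
            rate = spine_sink_rate(
                spine.neck_radius, v_comp, system.D_ca, system.dendrite_radius
            )
            for pos in spine.positions:
                w = footprint_weights(grid, self.dx, pos, spine.neck_radius)
                k_sp += rate * w * (w > 0)
            if spine.density > 0:
                k_sp += spine.density * rate * 2 * spine.neck_radius
        self.k_spine = k_sp
        # NMDA footprint (constant in time)
        if system.synapse is not None:
            syn = system.synapse
            self.syn_w = footprint_weights(grid, self.dx, syn.position, syn.receptor_radius)
        else:
            self.syn_w = None

    # -- helpers -------------------------------------------------------

    def _pump_loss_and_slope(self, u_ca):
        """Total pump loss density (particles/(μm s)) and its ∂/∂u_ca."""
        sysm = self.sys
        u = np.clip(u_ca, 0.0, None)
        c = self.gamma * u
        loss = np.zeros_like(u)
        slope = np.zeros_like(u)
        for p in sysm.pumps:
            sat = p.rate_per_pump * p.surface_density * sysm.perimeter
            ch = c**p.hill
            kh = p.K_half**p.hill
            denom = kh + ch + 1e-300
            loss += sat * ch / denom
            # d/du [c^h/(K^h+c^h)] = h K^h c^{h-1} γ / denom²
            with np.errstate(divide="ignore", invalid="ignore"):
                cpow = np.where(c > 0, c ** (p.hill - 1.0), 1.0 if p.hill == 1.0 else 0.0)
            slope += sat * p.hill * kh * cpow * self.gamma / denom**2
        return loss, slope

    def rhs(self, t, y):
        sysm = self.sys
        nx = self.nx
        lay = self.layout
        dy = np.zeros_like(y)
        u_ca = y[lay["ca"]]
        # diffusion of free calcium (reflecting ends)
        d_over = sysm.D_ca / self.dx**2
        lap = np.empty(nx)
        lap[1:-1] = u_ca[2:] - 2 * u_ca[1:-1] + u_ca[:-2]
        lap[0] = u_ca[1] - u_ca[0]
        lap[-1] = u_ca[-2] - u_ca[-1]
        du_ca = d_over * lap
        # buffers
        for buf in sysm.buffers:
            sl, n_states = lay["buffers"][buf.name]
            u_b = y[sl].reshape(n_states, nx)
            du_b = np.zeros_like(u_b)
            c_ca = self.gamma * u_ca
            for j in range(1, n_states):
                net = buf.k_forward[j - 1] * c_ca * u_b[j - 1] - buf.k_backward[j - 1] * u_b[j]
                du_b[j - 1] -= net
                du_b[j] += net
                du_ca -= net
            if buf.diffusion > 0:
                bd = buf.diffusion / self.dx**2
                for j in range(n_states):
                    row = u_b[j]
                    l = np.empty(nx)
                    l[1:-1] = row[2:] - 2 * row[1:-1] + row[:-2]
                    l[0] = row[1] - row[0]
                    l[-1] = row[-2] - row[-1]
                    du_b[j] += bd * l
            dy[sl] = du_b.ravel()
        # dye
        if sysm.dye is not None:
            u_d = y[lay["dye"]]
            u_total = concentration_to_linear_density(
                sysm.dye.total_concentration, sysm.cross_section
            )
            net = sysm.dye.k_forward * self.gamma * u_ca * (u_total - u_d) - sysm.dye.k_backward * u_d
            dy[lay["dye"]] = net
            du_ca -= net
        # pumps and spines
        pump_loss, _ = self._pump_loss_and_slope(u_ca)
        spine_loss = self.k_spine * np.clip(u_ca, 0.0, None)
        du_ca -= pump_loss + spine_loss
        # synaptic input
        inj_total = 0.0
        if self.syn_w is not None:
            syn = sysm.synapse
            ions = current_to_ion_rate(float(nmda_current(t, syn)), syn.ca_fraction)
            du_ca += ions * self.syn_w / self.dx
            inj_total = ions
        dy[lay["ca"]] = du_ca
        acc = lay["accumulators"]
        dy[acc["pumped"]] = pump_loss.sum() * self.dx
        dy[acc["spines"]] = spine_loss.sum() * self.dx
        dy[acc["injected"]] = inj_total
        return dy

    def jac(self, t, y):
        sysm = self.sys
        nx = self.nx
        lay = self.layout
        n_blocks = lay["n_blocks"]
        N = n_blocks * nx
        u_ca = y[lay["ca"]]
        c_ca = self.gamma * u_ca

        diags: dict[int, np.ndarray] = {}

        def add(rb: int, cb: int, vals: np.ndarray) -> None:
            off = (cb - rb) * nx
            arr = diags.setdefault(off, np.zeros(N))
            arr[rb * nx : (rb + 1) * nx] += vals

        # diffusion of calcium: tridiagonal in the ca block
        d_over = sysm.D_ca / self.dx**2
        main = np.full(nx, -2.0 * d_over)
        main[0] = main[-1] = -d_over
        add(0, 0, main)
        off_p1 = diags.setdefault(1, np.zeros(N))
        off_m1 = diags.setdefault(-1, np.zeros(N))
        off_p1[0 : nx - 1] += d_over
        off_m1[1:nx] += d_over

        for buf in sysm.buffers:
            _, n_states = lay["buffers"][buf.name]
            base = lay["blocks"][buf.name]
            sl, _ = lay["buffers"][buf.name]
            u_b = y[sl].reshape(n_states, nx)
            for j in range(1, n_states):
                kfg = buf.k_forward[j - 1] * self.gamma
                kb = buf.k_backward[j - 1]
                p = base + j - 1
                q = base + j
                dnet_dca = kfg * u_b[j - 1]
                dnet_dp = kfg * u_ca
                # du_ca -= net
                add(0, 0, -dnet_dca)
                add(0, p, -dnet_dp)
                add(0, q, np.full(nx, kb))
                # du_b[j-1] -= net
                add(p, 0, -dnet_dca)
                add(p, p, -dnet_dp)
                add(p, q, np.full(nx, kb))
                # du_b[j] += net
                add(q, 0, dnet_dca)
                add(q, p, dnet_dp)
                add(q, q, np.full(nx, -kb))
            if buf.diffusion > 0:
                bd = buf.diffusion / self.dx**2
                for j in range(n_states):
                    b = base + j
                    m = np.full(nx, -2.0 * bd)
                    m[0] = m[-1] = -bd
                    add(b, b, m)
                    off_p1[b * nx : (b + 1) * nx - 1] += bd
                    off_m1[b * nx + 1 : (b + 1) * nx] += bd

        if sysm.dye is not None:
            b = lay["blocks"]["dye"]
            u_d = y[lay["dye"]]
            u_total = concentration_to_linear_density(
                sysm.dye.total_concentration, sysm.cross_section
            )
            kfg = sysm.dye.k_forward * self.gamma
            kb = sysm.dye.k_backward
            dnet_dca = kfg * (u_total - u_d)
            dnet_dd = -kfg * u_ca - kb
            add(0, 0, -dnet_dca)
            add(0, b, -dnet_dd)
            add(b, 0, dnet_dca)
            add(b, b, dnet_dd)

        _, pump_slope = self._pump_loss_and_slope(u_ca)
        add(0, 0, -(pump_slope + self.k_spine))

        data, offsets = [], []
        for off, arr in diags.items():
            offsets.append(off)
            if off >= 0:
                data.append(arr[: N - off])
            else:
                data.append(arr[-off:])
        J_core = sp.diags_array(data, offsets=offsets, shape=(N, N), format="csr")

        # accumulator rows (pumped / spines depend on u_ca; nothing depends
        # on the accumulators themselves)
        rows = sp.lil_array((3, N))
        rows[0, :nx] = pump_slope * self.dx
        rows[1, :nx] = self.k_spine * self.dx
        J = sp.vstack([J_core, rows.tocsr()], format="csr")
        return _pad_cols(J, 3)


def _pad_cols(m: sp.csr_array, k: int) -> sp.csr_array:
    """Append k empty columns to a sparse matrix."""
    return sp.hstack([m, sp.csr_array((m.shape[0], k))], format="csr")


def initial_state(system: ReactionSystemSpec, grid: np.ndarray, layout: dict,
                  ca_profile=None) -> np.ndarray:
    """Flat initial state: baseline-equilibrated buffers plus a Ca profile.

    ``ca_profile`` maps position (μm) → added free calcium in μM.
    """
    from .kinetics import buffer_equilibrium

    nx = grid.size
    y0 = np.zeros(layout["n_state"])
    base = system.baseline_ca
    u_base = concentration_to_linear_density(base, system.cross_section)
    added = np.zeros(nx)
    if ca_profile is not None:
        added = concentration_to_linear_density(
            np.asarray([ca_profile(x) for x in grid], dtype=float),
            system.cross_section,
        )
    y0[layout["ca"]] = u_base + added
    for buf in system.buffers:
        sl, n_states = layout["buffers"][buf.name]
        u_total = concentration_to_linear_density(
            buf.total_concentration, system.cross_section
        )
        occ = buffer_equilibrium(buf, base)
        states = np.repeat(occ[:, None] * u_total, nx, axis=1)
        y0[sl] = states.ravel()
    if system.dye is not None and base > 0:
        u_total = concentration_to_linear_density(
            system.dye.total_concentration, system.cross_section
        )
        kd = system.dye.k_backward / system.dye.k_forward
        y0[layout["dye"]] = u_total * base / (kd + base)
    return y0


def assemble_and_solve(
    system: ReactionSystemSpec,
    t_end: float,
    ca_profile=None,
    n_save: int = 101,
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "BDF",
) -> CalciumTrajectory:
    """Integrate the calcium system from an equilibrated initial condition.

    Parameters
    ----------
    ca_profile
        Optional callable x (μm) → initial added free calcium (μM), e.g. a
        pipette/uncaging pulse.
    """
    nx = int(round(system.length / system.dx)) + 1
    grid = np.linspace(0.0, system.length, nx)
    layout = _build_layout(system, nx)
    asm = _Assembler(system, grid, layout)
    y0 = initial_state(system, grid, layout, ca_profile)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_save)
    sol = solve_ivp(
        asm.rhs,
        (0.0, t_end),
        y0,
        method=method,
        jac=asm.jac,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"stiff solver failed: {sol.message} (nfev={sol.nfev}, njev={sol.njev})"
        )
    return CalciumTrajectory(sol.t, sol.y.T, grid, system, layout)
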