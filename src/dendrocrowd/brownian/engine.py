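"""Adaptive-step Euler Brownian dynamics with exact ray-traced reflections.

Each particle carries its own physical clock.  Steps are Gaussian with
per-axis variance 2·D·dt where dt adapts to the distance from the nearest
surface; segments that cross a surface are reflected specularly (possibly
several times within one step) or absorbed, with the absorption time
interpolated along the path.  Particle clocks are reconciled with the
sampling grid by clipping the last step of each particle exactly onto the
next sampling tick.

The kernels are compiled with numba; the barrier lookup can run either
through a sorted-array bisection (the acceleration structure) or by brute
force over all barriers — both produce bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .scene import Scene, SimConfig

_ACTIVE, _ABSORBED = 0, 1


@njit(cache=True)
def _seed(seed):  # numba's RNG state is global; seed once per run
    np.random.seed(seed)


@njit(cache=True, fastmath=True, inline="always")
def _first_blocking_barrier(px, py, pz, dx, dy, dz, t0, a2, xb, hr, hyc, hzc, use_part):
    """First barrier-plane crossing along the sub-segment that does NOT
    pass through the hole.  Returns (t, index) or (2.0, -1)."""
    nb = xb.shape[0]
    if nb == 0 or dx == 0.0:
        return 2.0, -1
    qx = px + dx
    if dx > 0.0:
        lo = np.searchsorted(xb, px, side="right") if use_part else 0
        for i in range(lo, nb):
            if not use_part and xb[i] <= px:
                continue
            if xb[i] >= qx:
                break
            t = (xb[i] - px) / dx
            if t <= t0 or t > 1.0:
                continue
            hy = py + t * dy
            hz = pz + t * dz
            if hy * hy + hz * hz > a2:
                continue  # plane does not extend outside the dendrite
            ddy = hy - hyc[i]
            ddz = hz - hzc[i]
            if ddy * ddy + ddz * ddz >= hr[i] * hr[i]:
                return t, i
    else:
        hi = np.searchsorted(xb, px, side="left") if use_part else nb
        for i in range(hi - 1, -1, -1):
            if not use_part and xb[i] >= px:
                continue
            if xb[i] <= qx:
                break
            t = (xb[i] - px) / dx
            if t <= t0 or t > 1.0:
                continue
            hy = py + t * dy
            hz = pz + t * dz
            if hy * hy + hz * hz > a2:
                continue
            ddy = hy - hyc[i]
            ddz = hz - hzc[i]
            if ddy * ddy + ddz * ddz >= hr[i] * hr[i]:
                return t, i
    return 2.0, -1


@njit(cache=True, fastmath=True, inline="always")
def _outward_root(A, B, C):
    """Largest real root of A t² + B t + C = 0 (the outward crossing of an
    upward parabola); 2.0 if none."""
    if A <= 0.0:
        return 2.0
    disc = B * B - 4.0 * A * C
    if disc <= 0.0:
        return 2.0
    return (-B + math.sqrt(disc)) / (2.0 * A)


@njit(cache=True, fastmath=True)
def _trace(
    px, py, pz, qx, qy, qz,
    a, ltot,
    xb, hr, hyc, hzc,
    end0, end1, wrad,
    has_spine, xs, rn, ztop, zc, rh, head_abs,
    use_part,
):
    """Trace one Gaussian step from p to q through the scene.

    Returns (x, y, z, code, frac): code 0 = still active, 1 = absorbed,
    2 = reflection budget exhausted (particle parked on the boundary);
    frac is the fraction of the step length travelled when absorbed.
    """
    a2 = a * a
    rn2 = rn * rn
    rh2 = rh * rh
    f_done = 0.0
    push = 1e-9
    for _ in range(128):
        dx = qx - px
        dy = qy - py
        dz = qz - pz
        t0 = 1e-12
        best_t = 2.0
        best_kind = -1
        best_aux = -1

        # end caps
        if qx < 0.0 and px >= 0.0 and dx != 0.0:
            t = -px / dx
            if t0 < t <= 1.0 and t < best_t:
                best_t = t
                best_kind = 0
        if qx > ltot and px <= ltot and dx != 0.0:
            t = (ltot - px) / dx
            if t0 < t <= 1.0 and t < best_t:
                best_t = t
                best_kind = 1

        # lateral wall (outward crossings only)
        A = dy * dy + dz * dz
        B = 2.0 * (py * dy + pz * dz)
        C = py * py + pz * pz - a2
        t = _outward_root(A, B, C)
        if t0 < t <= 1.0 and t < best_t:
            hx = px + t * dx
            hy = py + t * dy
            hz = pz + t * dz
            blocking = True
            if has_spine and hz > 0.0:
                ex = hx - xs
                if ex * ex + hy * hy < rn2 and 0.0 < hx < ltot:
                    blocking = False  # passes into the spine neck
            if blocking:
                best_t = t
                best_kind = 2

        # barrier disks
        tb, ib = _first_blocking_barrier(
            px, py, pz, dx, dy, dz, t0, a2, xb, hr, hyc, hzc, use_part
        )
        if tb <= 1.0 and tb < best_t:
            best_t = tb
            best_kind = 3
            best_aux = ib

        if has_spine:
            # neck cylinder wall
            An = dx * dx + dy * dy
            Bn = 2.0 * ((px - xs) * dx + py * dy)
            Cn = (px - xs) * (px - xs) + py * py - rn2
            t = _outward_root(An, Bn, Cn)
            if t0 < t <= 1.0 and t < best_t:
                hy = py + t * dy
                hz = pz + t * dz
                # a real wall only outside the dendrite and below the head
                if hy * hy + hz * hz >= a2 and hz <= ztop:
                    best_t = t
                    best_kind = 4
            # head sphere
            Ah = dx * dx + dy * dy + dz * dz
            Bh = 2.0 * ((px - xs) * dx + py * dy + (pz - zc) * dz)
            Ch = (px - xs) * (px - xs) + py * py + (pz - zc) * (pz - zc) - rh2
            t = _outward_root(Ah, Bh, Ch)
            if t0 < t <= 1.0 and t < best_t:
                hx = px + t * dx
                hy = py + t * dy
                hz = pz + t * dz
                ex = hx - xs
                in_neck = ex * ex + hy * hy <= rn2 and hz <= ztop
                if not in_neck:
                    best_t = t
                    best_kind = 5

        if best_kind < 0:
            return qx, qy, qz, 0, 1.0

        hx = px + best_t * dx
        hy = py + best_t * dy
        hz = pz + best_t * dz
        f_abs = f_done + (1.0 - f_done) * best_t

        if best_kind == 0:  # x = 0 cap
            if end0 == 1 or (end0 == 2 and hy * hy + hz * hz <= wrad * wrad):
                return hx, hy, hz, 1, f_abs
            qx = -qx
            px, py, pz = push, hy, hz
        elif best_kind == 1:  # x = ltot cap
            if end1 == 1 or (end1 == 2 and hy * hy + hz * hz <= wrad * wrad):
                return hx, hy, hz, 1, f_abs
            qx = 2.0 * ltot - qx
            px, py, pz = ltot - push, hy, hz
        elif best_kind == 2:  # lateral wall
            ny = hy / a
            nz = hz / a
            vx = qx - hx
            vy = qy - hy
            vz = qz - hz
            vn = vy * ny + vz * nz
            qx = hx + vx
            qy = hy + (vy - 2.0 * vn * ny)
            qz = hz + (vz - 2.0 * vn * nz)
            px = hx
            py = hy - push * ny
            pz = hz - push * nz
        elif best_kind == 3:  # barrier disk
            bx = xb[best_aux]
            qx = 2.0 * bx - qx
            sgn = 1.0 if dx > 0.0 else -1.0
            px = bx - sgn * push
            py, pz = hy, hz
        elif best_kind == 4:  # spine neck wall
            nx = (hx - xs) / rn
            ny = hy / rn
            vx = qx - hx
            vy = qy - hy
            vz = qz - hz
            vn = vx * nx + vy * ny
            qx = hx + (vx - 2.0 * vn * nx)
            qy = hy + (vy - 2.0 * vn * ny)
            qz = hz + vz
            px = hx - push * nx
            py = hy - push * ny
            pz = hz
        else:  # head sphere
            if head_abs:
                return hx, hy, hz, 1, f_abs
            nx = (hx - xs) / rh
            ny = hy / rh
            nz = (hz - zc) / rh
            vx = qx - hx
            vy = qy - hy
            vz = qz - hz
            vn = vx * nx + vy * ny + vz * nz
            qx = hx + (vx - 2.0 * vn * nx)
            qy = hy + (vy - 2.0 * vn * ny)
            qz = hz + (vz - 2.0 * vn * nz)
            px = hx - push * nx
            py = hy - push * ny
            pz = hz - push * nz
        f_done = f_abs
    return px, py, pz, 2, f_done


@njit(cache=True, fastmath=True)
def _advance(
    pos, clock, status, abs_times,
    t_stop,
    D, frac, dt_min, dt_max,
    a, ltot,
    xb, hr, hyc, hzc,
    end0, end1, wrad,
    has_spine, xs, rn, ztop, zc, rh, head_abs,
    use_part,
):
    """Advance every active particle to physical time ``t_stop``."""
    n = pos.shape[0]
    six_d = 6.0 * D if D > 0.0 else 1.0
    n_parked = 0
    for i in range(n):
        if status[i] != _ACTIVE:
            continue
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        t = clock[i]
        while t < t_stop:
            # Step control: only surfaces whose handling degrades with step
            # size matter.  Specular reflection off walls and reflecting
            # caps is exact for straight segments, so those surfaces do not
            # constrain dt.  Barrier disks do (the hole pass/block decision
            # must be resolved at the hole scale), as do spine surfaces.
            # Absorbing surfaces constrain dt *without a floor*: otherwise
            # the straight-segment tracer misses Brownian-bridge crossings
            # and biases first-passage times upward.
            ryz = math.sqrt(y * y + z * z)
            d = 1e30
            d_abs = 1e30
            dist0 = x
            dist1 = ltot - x
            if end0 == 1:
                d_abs = dist0
            elif end0 == 2:
                lat = ryz - wrad
                if lat < 0.0:
                    lat = 0.0
                dw = math.sqrt(dist0 * dist0 + lat * lat)
                if dw < d_abs:
                    d_abs = dw
            if end1 == 1:
                if dist1 < d_abs:
                    d_abs = dist1
            elif end1 == 2:
                lat = ryz - wrad
                if lat < 0.0:
                    lat = 0.0
                dw = math.sqrt(dist1 * dist1 + lat * lat)
                if dw < d_abs:
                    d_abs = dw
            nb = xb.shape[0]
            if nb > 0:
                j = np.searchsorted(xb, x)
                if j < nb and xb[j] - x < d:
                    d = xb[j] - x
                if j > 0 and x - xb[j - 1] < d:
                    d = x - xb[j - 1]
            if has_spine:
                rne = math.sqrt((x - xs) * (x - xs) + y * y)
                if abs(rn - rne) < d:
                    d = abs(rn - rne)
                dc = math.sqrt((x - xs) * (x - xs) + y * y + (z - zc) * (z - zc))
                if head_abs:
                    if abs(rh - dc) < d_abs:
                        d_abs = abs(rh - dc)
                elif abs(rh - dc) < d:
                    d = abs(rh - dc)
            if d < 1e-6:
                d = 1e-6
            dt = dt_max
            if d < 1e29:
                dt = (frac * d) * (frac * d) / six_d
                if dt < dt_min:
                    dt = dt_min
            if d_abs < 1e30:
                dta = (frac * d_abs) * (frac * d_abs) / six_d
                if dta < 1e-3 * dt_min:
                    dta = 1e-3 * dt_min
                if dta < dt:
                    dt = dta
            if dt > dt_max:
                dt = dt_max
            if t + dt > t_stop:
                dt = t_stop - t
            s = math.sqrt(2.0 * D * dt)
            qx = x + s * np.random.normal()
            qy = y + s * np.random.normal()
            qz = z + s * np.random.normal()
            x, y, z, code, f = _trace(
                x, y, z, qx, qy, qz,
                a, ltot,
                xb, hr, hyc, hzc,
                end0, end1, wrad,
                has_spine, xs, rn, ztop, zc, rh, head_abs,
                use_part,
            )
            if code == 1:
                status[i] = _ABSORBED
                abs_times[i] = t + f * dt
                break
            if code == 2:
                n_parked += 1
            t += dt
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
        clock[i] = t_stop if status[i] == _ACTIVE else abs_times[i]
    return n_parked


@dataclass
class ParticleEnsemble:
    """Positions, statuses and per-particle clocks of the walker swarm."""

    positions: np.ndarray
    status: np.ndarray
    clock: np.ndarray
    absorption_times: np.ndarray

    @property
    def n_active(self) -> int:
        return int(np.sum(self.status == _ACTIVE))

    @property
    def n_absorbed(self) -> int:
        return int(np.sum(self.status == _ABSORBED))

    def in_spine(self, scene: Scene) -> np.ndarray:
        """Active particles currently inside the spine (outside the shaft)."""
        p = self.positions
        outside_shaft = p[:, 1] ** 2 + p[:, 2] ** 2 > scene.cylinder_radius**2
        return (self.status == _ACTIVE) & outside_shaft


def _scene_args(scene: Scene, config: SimConfig):
    xb = scene.barriers
    hr = scene.hole_radii
    yz = scene.hole_yz
    end_map = {"reflecting": 0, "absorbing": 1, "window": 2}
    end0 = end_map[scene.end_conditions[0]]
    end1 = end_map[scene.end_conditions[1]]
    if scene.spine is not None:
        s = scene.spine
        ztop = math.sqrt(scene.cylinder_radius**2 - s.neck_radius**2) + s.neck_length
        zc = ztop + math.sqrt(s.head_radius**2 - s.neck_radius**2)
        spine_args = (True, s.attach_position, s.neck_radius, ztop, zc, s.head_radius, s.head_absorbing)
    else:
        spine_args = (False, 0.0, 0.0, 0.0, 0.0, 0.0, False)
    return (
        scene.cylinder_radius,
        scene.cylinder_length,
        xb, hr, yz[:, 0].copy(), yz[:, 1].copy(),
        end0, end1, scene.window_radius,
        *spine_args,
        config.use_partition,
    )


def _dt_bounds(scene: Scene, config: SimConfig) -> tuple[float, float]:
    if config.D <= 0:
        return config.base_step, config.base_step
    dmin = config.adaptive_min_fraction * scene.smallest_length
    return dmin * dmin / (6.0 * config.D), config.base_step


def initialize_ensemble(
    scene: Scene,
    config: SimConfig,
    axial_profile=None,
    x_range: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> ParticleEnsemble:
    """Seed particles inside the dendritic shaft.

    ``axial_profile`` is an optional callable giving the (unnormalized)
    axial density; the radial placement is uniform over the cross-section
    ("homogeneous in the radial direction").  Without a profile, particles
    are uniform over ``x_range`` (default: the whole cylinder).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_particles
    lo, hi = x_range if x_range is not None else (0.0, scene.cylinder_length)
    if axial_profile is None:
        x = rng.uniform(lo, hi, size=n)
    else:
        grid = np.linspace(lo, hi, 2048)
        w = np.clip(np.asarray([axial_profile(g) for g in grid], dtype=float), 0, None)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        x = np.interp(rng.uniform(size=n), cdf, grid)
    r = scene.cylinder_radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    pos = np.column_stack([x, r * np.cos(th), r * np.sin(th)])
    return ParticleEnsemble(
        positions=pos,
        status=np.zeros(n, dtype=np.int8),
        clock=np.zeros(n),
        absorption_times=np.full(n, np.nan),
    )


def step_ensemble(
    ensemble: ParticleEnsemble,
    scene: Scene,
    config: SimConfig,
    duration: float,
    _seeded: bool = False,
) -> ParticleEnsemble:
    """Advance all active particles by ``duration`` seconds (in place)."""
    if not _seeded:
        _seed(config.rng_seed)
    dt_min, dt_max = _dt_bounds(scene, config)
    t_stop = float(ensemble.clock.max()) + duration if ensemble.positions.size else duration
    n_parked = _advance(
        ensemble.positions, ensemble.clock, ensemble.status, ensemble.absorption_times,
        t_stop,
        config.D, config.adaptive_min_fraction, dt_min, dt_max,
        *_scene_args(scene, config),
    )
    active = ensemble.status == _ACTIVE
    if np.any(active) and not np.all(scene.contains(ensemble.positions[active])):
        raise RuntimeError(
            f"particle escaped the domain (tracing bug guard); seed={config.rng_seed}"
        )
    if n_parked:  # pragma: no cover - diagnostic only
        import warnings

        warnings.warn(f"{n_parked} step(s) exhausted the reflection budget")
    return ensemble


@dataclass
class Trajectory:
    """Axial particle positions recorded on the sampling-tick grid."""

    times: np.ndarray
    x: np.ndarray          # (nt, N), NaN once absorbed
    active: np.ndarray     # (nt, N) bool
    in_shaft: np.ndarray   # (nt, N) bool: active and inside the main cylinder
    ensemble: ParticleEnsemble
    scene: Scene = field(repr=False, default=None)
    config: SimConfig = field(repr=False, default=None)


def run_linescan(
    scene: Scene,
    config: SimConfig,
    duration: float,
    axial_profile=None,
    x_range: tuple | None = None,
) -> Trajectory:
    """Simulate and record axial positions at every sampling tick."""
    ens = initialize_ensemble(scene, config, axial_profile, x_range)
    _seed(config.rng_seed)
    n_ticks = int(round(duration / config.sampling_period)) + 1
    times = np.arange(n_ticks) * config.sampling_period
    n = config.n_particles
    xs = np.full((n_ticks, n), np.nan)
    act = np.zeros((n_ticks, n), dtype=bool)
    shaft = np.zeros((n_ticks, n), dtype=bool)

    def record(k):
        active = ens.status == _ACTIVE
        xs[k, active] = ens.positions[active, 0]
        act[k] = active
        shaft[k] = active & (
            ens.positions[:, 1] ** 2 + ens.positions[:, 2] ** 2
            <= scene.cylinder_radius**2
        )

    record(0)
    for k in range(1, n_ticks):
        step_ensemble(ens, scene, config, config.sampling_period, _seeded=True)
        record(k)
    return Trajectory(times, xs, act, shaft, ens, scene, config)


def run_mfpt(
    scene: Scene,
    config: SimConfig,
    t_cap: float,
    x_range: tuple | None = None,
) -> ParticleEnsemble:
    """Run until absorption or ``t_cap``; initial positions uniform."""
    ens = initialize_ensemble(scene, config, x_range=x_range)
    step_ensemble(ens, scene, config, t_cap)
    return ens
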