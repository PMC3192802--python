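"""Analytic scene geometry for the Brownian simulator.

Surfaces are exact analytic primitives — cylinder wall, end caps, planar
annular barriers with a circular hole, and an optional spine built from a
radial neck cylinder and a spherical head — rather than triangle meshes;
ray/surface intersections are solved in closed form, which removes mesh
discretization artifacts from the oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

_END_CONDITIONS = ("reflecting", "absorbing", "window")


@dataclass(frozen=True)
class SpineGeometry:
    """Passive spine: radial cylindrical neck topped by a spherical head.

    The neck meets the dendrite wall tangentially (opening area π·r_neck²)
    at axial position ``attach_position`` and extends radially by
    ``neck_length``; the head sphere is placed so that its cross-section
    where it meets the neck equals the neck cross-section.
    """

    attach_position: float
    neck_radius: float = 0.3
    neck_length: float = 0.2
    head_radius: float = 0.4
    head_absorbing: bool = False

    def __post_init__(self) -> None:
        if min(self.neck_radius, self.neck_length, self.head_radius) <= 0:
            raise ValueError("spine dimensions must be positive")
        if self.head_radius < self.neck_radius:
            raise ValueError(
                f"head radius {self.head_radius} must be at least the neck "
                f"radius {self.neck_radius}"
            )


@dataclass(frozen=True)
class SamplingVolume:
    """Full-cross-section cylindrical disk used to record concentrations."""

    center_x: float
    height: float = 0.6

    @property
    def x_min(self) -> float:
        return self.center_x - 0.5 * self.height

    @property
    def x_max(self) -> float:
        return self.center_x + 0.5 * self.height


@dataclass(frozen=True)
class SimConfig:
    """Stepping and sampling parameters of the Brownian engine.

    The Euler step is adaptive: dt = (fraction · d)² / (6D) for distance d
    to the nearest surface, clipped to [dt_min, base_step] where dt_min is
    set by the smallest geometric length scale of the scene.
    """

    D: float = 400.0
    n_particles: int = 10_000
    base_step: float = 1e-5
    adaptive_min_fraction: float = 0.4
    sampling_period: float = 0.7e-3
    rng_seed: int = 0
    use_partition: bool = True

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if not 0.3 <= self.adaptive_min_fraction <= 0.5:
            raise ValueError(
                "adaptive_min_fraction outside the supported band [0.3, 0.5]"
            )
        if self.base_step <= 0 or self.sampling_period <= 0:
            raise ValueError("time steps must be positive")


@dataclass(frozen=True)
class Scene:
    """Cylindrical dendrite with barrier disks and optional spine.

    Attributes
    ----------
    cylinder_radius, cylinder_length : μm
    barrier_positions : axial positions of barrier disks, strictly inside
        the cylinder and sorted.
    hole_radius : one opening radius per barrier (μm).
    hole_centers : per-barrier (y, z) of the opening center; the default
        policy is axis-centered, a randomized policy is available in
        :func:`make_calibrated_scene`.
    end_conditions : condition at x=0 and x=L_total; ``"window"`` means a
        reflecting cap with a centered absorbing disk of radius
        ``window_radius``.
    """

    cylinder_radius: float
    cylinder_length: float
    barrier_positions: tuple = ()
    hole_radius: tuple = ()
    hole_centers: tuple = ()
    end_conditions: tuple = ("reflecting", "reflecting")
    window_radius: float = 0.0
    spine: SpineGeometry | None = None

    def __post_init__(self) -> None:
        a, lt = self.cylinder_radius, self.cylinder_length
        if a <= 0 or lt <= 0:
            raise ValueError("cylinder dimensions must be positive")
        xb = np.asarray(self.barrier_positions, dtype=float)
        hr = np.asarray(self.hole_radius, dtype=float)
        if xb.size != hr.size:
            raise ValueError("one hole radius per barrier required")
        if xb.size and (np.any(xb <= 0) or np.any(xb >= lt)):
            raise ValueError("barriers must lie strictly inside the cylinder")
        if xb.size and np.any(np.diff(xb) <= 0):
            raise ValueError("barrier positions must be strictly increasing")
        if np.any(hr >= a) or np.any(hr <= 0):
            raise ValueError("hole radii must satisfy 0 < eps < cylinder radius")
        centers = np.asarray(self.hole_centers, dtype=float).reshape(-1, 2)
        if self.hole_centers and centers.shape[0] != xb.size:
            raise ValueError("one hole center per barrier required")
        if self.hole_centers:
            rim = np.hypot(centers[:, 0], centers[:, 1]) + hr
            if np.any(rim > a):
                raise ValueError("hole must lie fully inside the cross-section")
        for ec in self.end_conditions:
            if ec not in _END_CONDITIONS:
                raise ValueError(f"unknown end condition {ec!r}")
        if "window" in self.end_conditions and not 0 < self.window_radius < a:
            raise ValueError("window end condition requires 0 < window_radius < a")
        if self.spine is not None:
            if not 0 < self.spine.attach_position < lt:
                raise ValueError("spine attach position outside the cylinder")
            if self.spine.neck_radius >= a:
                raise ValueError("spine neck wider than the dendrite")

    # -- geometry queries ------------------------------------------------

    @property
    def barriers(self) -> np.ndarray:
        return np.asarray(self.barrier_positions, dtype=float)

    @property
    def hole_radii(self) -> np.ndarray:
        return np.asarray(self.hole_radius, dtype=float)

    @property
    def hole_yz(self) -> np.ndarray:
        if self.hole_centers:
            return np.asarray(self.hole_centers, dtype=float).reshape(-1, 2)
        return np.zeros((len(self.barrier_positions), 2))

    @property
    def smallest_length(self) -> float:
        cands = [self.cylinder_radius]
        if len(self.barrier_positions):
            cands.append(float(np.min(self.hole_radii)))
            cands.append(float(np.min(np.diff(np.r_[0.0, self.barriers, self.cylinder_length]))))
        if self.window_radius > 0:
            cands.append(self.window_radius)
        if self.spine is not None:
            cands.append(self.spine.neck_radius)
        return min(cands)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-membership test for the domain union."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        inside = (
            (x >= 0)
            & (x <= self.cylinder_length)
            & (y**2 + z**2 <= self.cylinder_radius**2)
        )
        if self.spine is not None:
            s = self.spine
            z_top = math.sqrt(self.cylinder_radius**2 - s.neck_radius**2) + s.neck_length
            zc = z_top + math.sqrt(s.head_radius**2 - s.neck_radius**2)
            in_neck = (
                ((x - s.attach_position) ** 2 + y**2 <= s.neck_radius**2)
                & (z >= 0)
                & (z <= z_top)
            )
            in_head = (x - s.attach_position) ** 2 + y**2 + (z - zc) ** 2 <= s.head_radius**2
            inside |= in_neck | in_head
        return inside if points.ndim > 1 else inside[0]

    def to_json(self) -> str:
        """Simple JSON geometry listing for inspection."""
        d = {
            "cylinder_radius_um": self.cylinder_radius,
            "cylinder_length_um": self.cylinder_length,
            "barriers": [
                {"x_um": float(x), "hole_radius_um": float(r), "hole_center_yz": list(map(float, c))}
                for x, r, c in zip(self.barriers, self.hole_radii, self.hole_yz)
            ],
            "end_conditions": list(self.end_conditions),
            "window_radius_um": self.window_radius,
            "spine": None
            if self.spine is None
            else {
                "attach_position_um": self.spine.attach_position,
                "neck_radius_um": self.spine.neck_radius,
                "neck_length_um": self.spine.neck_length,
                "head_radius_um": self.spine.head_radius,
                "head_absorbing": self.spine.head_absorbing,
            },
        }
        return json.dumps(d, indent=2)


def build_scene(config: dict) -> Scene:
    """Construct a :class:`Scene` from a plain configuration mapping."""
    spine_cfg = config.get("spine")
    spine = SpineGeometry(**spine_cfg) if spine_cfg else None
    return Scene(
        cylinder_radius=config["cylinder_radius"],
        cylinder_length=config["cylinder_length"],
        barrier_positions=tuple(config.get("barrier_positions", ())),
        hole_radius=tuple(config.get("hole_radius", ())),
        hole_centers=tuple(map(tuple, config.get("hole_centers", ()))),
        end_conditions=tuple(config.get("end_conditions", ("reflecting", "reflecting"))),
        window_radius=config.get("window_radius", 0.0),
        spine=spine,
    )


def make_calibrated_scene(
    spec,
    total_length: float,
    end_conditions: tuple = ("reflecting", "reflecting"),
    spine: SpineGeometry | None = None,
    jitter_sigma: float = 0.0,
    hole_center_policy: str = "axis",
    rng: np.random.Generator | None = None,
) -> Scene:
    """Barrier scene realizing a calibrated compartment geometry.

    Places ``floor(total_length / L) − 1`` barrier disks of hole radius ε
    at spacing L (optionally jittered by N(0, σ²) displacements, clipped
    so barrier order is preserved).  ``hole_center_policy`` is ``"axis"``
    or ``"random"`` (uniform over the admissible disk).
    """
    n_comp = int(math.floor(total_length / spec.L))
    if n_comp < 2:
        raise ValueError("total length must span at least two compartments")
    xb = np.arange(1, n_comp) * spec.L
    if jitter_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        xb = xb + rng.normal(0.0, jitter_sigma, size=xb.size)
        xb = np.sort(np.clip(xb, 0.05 * spec.L, total_length - 0.05 * spec.L))
        keep = np.r_[True, np.diff(xb) > 2 * spec.eps]
        xb = xb[keep]
    if hole_center_policy == "axis":
        centers = tuple((0.0, 0.0) for _ in xb)
    elif hole_center_policy == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        r_max = spec.a - spec.eps
        rr = r_max * np.sqrt(rng.uniform(size=xb.size))
        th = rng.uniform(0, 2 * math.pi, size=xb.size)
        centers = tuple((float(r * math.cos(t)), float(r * math.sin(t))) for r, t in zip(rr, th))
    else:
        raise ValueError(f"unknown hole center policy {hole_center_policy!r}")
    return Scene(
        cylinder_radius=spec.a,
        cylinder_length=total_length,
        barrier_positions=tuple(float(x) for x in xb),
        hole_radius=tuple(float(spec.eps) for _ in xb),
        hole_centers=centers,
        end_conditions=end_conditions,
        spine=spine,
    )
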