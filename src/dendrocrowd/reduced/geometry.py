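"""Compartment geometry, the compartment parameter and its calibration."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

from ..units import cross_section_area

#: default upper bound on ε/L for the small-hole approximation to stay
#: accurate to ~5% (checked against the Brownian oracle in the test suite)
SMALL_HOLE_VALIDITY_BOUND = 0.15

#: default calibration ratio ε/L, chosen so that the first-order
#: small-hole MFPT stays within ~5% of the Brownian escape time at the
#: calibrated geometry (the stated validity criterion of the reduction)
DEFAULT_CALIBRATION_RATIO = 0.035


class CalibrationError(ValueError):
    """Raised when no admissible (L, ε) pair exists for a requested target."""


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry of the periodic-barrier crowding model.

    Attributes
    ----------
    L : μm
        Compartment length (barrier spacing).
    eps : μm
        Radius of the opening connecting neighboring compartments.
    a : μm
        Dendrite radius.
    D : μm²/s
        Free (aqueous) diffusion constant.
    validity_bound
        Upper bound enforced on ε/L; beyond it the small-hole MFPT that
        underlies the reduction loses accuracy.
    strict
        If True (default) an out-of-band ε/L raises; otherwise it warns.
    """

    L: float
    eps: float
    a: float
    D: float
    validity_bound: float = SMALL_HOLE_VALIDITY_BOUND
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("L", "eps", "a", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.eps >= self.a:
            raise ValueError(
                f"opening radius eps={self.eps} must be smaller than the "
                f"dendrite radius a={self.a}"
            )
        ratio = self.eps / self.L
        if ratio > self.validity_bound:
            msg = (
                f"eps/L = {ratio:.3g} exceeds the small-hole validity bound "
                f"{self.validity_bound}"
            )
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def S(self) -> float:
        """Cross-sectional area π a² (μm²), always derived from ``a``."""
        return cross_section_area(self.a)

    @property
    def volume(self) -> float:
        """Compartment volume S·L (μm³)."""
        return self.S * self.L

    @property
    def escape_time(self) -> float:
        """Small-hole MFPT out of one compartment through one opening (s)."""
        from .narrow_escape import mfpt_escape_3d

        return mfpt_escape_3d(self.volume, self.eps, self.D)

    @property
    def hop_time(self) -> float:
        """Mean time 1/k of the inter-compartment hop, k = 2Dε/V (s).

        Twice the one-sided escape time: transmission through an aperture
        sees the access resistance of both sides.
        """
        return 2.0 * self.escape_time


def compartment_parameter(spec: CompartmentSpec) -> float:
    """Dimensionless ratio 2 ε L / S relating effective to free diffusion.

    Equal to D_eff / D.  Vanishes as ε → 0 (sealed compartments) and is
    invariant under rescalings (ε, L) → (ε/c, cL) that preserve the
    product εL.

    The prefactor comes from the diffusive conductance of the opening:
    a circular aperture of radius ε carries an access resistance
    1/(4Dε) on *each* side, so the inter-compartment conductance is
    2Dε and the hop rate per window is 2Dε/V — half the inverse
    one-sided narrow-escape time V/(4Dε), which describes absorption
    at the window rather than transmission through it.  This prefactor
    is verified against the 3D Brownian oracle in the test suite.
    """
    return 2.0 * spec.eps * spec.L / spec.S


def effective_diffusion_constant(spec: CompartmentSpec) -> float:
    """Effective 1D diffusion constant D_eff = (2εL/S)·D of the reduction.

    Diffusion limit of the compartment-chain master equation with the
    aperture hop rate k = 2Dε/V between neighbors and hop length L:
    D_eff = k L² = (2εL/S)·D, always smaller than the free constant D
    within the validity band.
    """
    return compartment_parameter(spec) * spec.D


def calibrate_geometry(
    target_ratio: float,
    a: float,
    calibration_ratio: float = DEFAULT_CALIBRATION_RATIO,
    D: float = 400.0,
    **spec_kwargs,
) -> CompartmentSpec:
    """Find (L, ε) giving a prescribed D_eff/D at a fixed aspect ratio ε/L.

    The compartment parameter 2εL/S fixes only the product εL; the second
    condition ε/L = ``calibration_ratio`` (default 0.035, inside the
    small-hole validity band) closes the system:

        L = sqrt(target·S / (2·ratio)),   ε = ratio · L.

    Raises
    ------
    CalibrationError
        If the target is not in (0, 1) or the resulting opening would not
        fit inside the cross-section (ε ≥ a).
    """
    if not 0 < target_ratio < 1:
        raise CalibrationError(
            f"target D_eff/D must lie strictly between 0 and 1, got {target_ratio}"
        )
    if calibration_ratio <= 0:
        raise CalibrationError(f"calibration ratio must be positive, got {calibration_ratio}")
    S = cross_section_area(a)
    L = math.sqrt(target_ratio * S / (2.0 * calibration_ratio))
    eps = calibration_ratio * L
    if eps >= a:
        raise CalibrationError(
            f"calibrated opening eps={eps:.4g} does not fit inside the "
            f"dendrite radius a={a}"
        )
    return CompartmentSpec(L=L, eps=eps, a=a, D=D, **spec_kwargs)


@dataclass(frozen=True)
class InhomogeneousProfile:
    """Spatially varying opening radius ε(x) and compartment volume V(x).

    Both callables must be strictly positive and smooth on ``domain``;
    derivatives are taken by central finite differences on the solver grid.
    """

    eps_of_x: Callable[[float], float]
    V_of_x: Callable[[float], float]
    domain: tuple[float, float] = (0.0, 100.0)
    fd_step: float = field(default=1e-4)

    def __post_init__(self) -> None:
        x0, x1 = self.domain
        if not x1 > x0:
            raise ValueError(f"empty domain {self.domain}")
        import numpy as np

        probe = np.linspace(x0, x1, 17)
        eps = np.asarray([self.eps_of_x(x) for x in probe], dtype=float)
        vol = np.asarray([self.V_of_x(x) for x in probe], dtype=float)
        if not (np.all(eps > 0) and np.all(vol > 0)):
            raise ValueError("eps_of_x and V_of_x must be strictly positive on the domain")

    def deps_dx(self, x):
        """Central-difference derivative of ε(x)."""
        import numpy as np

        h = self.fd_step
        f = np.vectorize(self.eps_of_x)
        return (f(x + h) - f(x - h)) / (2 * h)
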