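"""Small-hole (narrow-escape) mean first passage times.

First-order asymptotics for the mean time a Brownian particle needs to
escape a confining domain through an absorbing opening much smaller than
the domain itself.
"""

from __future__ import annotations

import math


def mfpt_escape_3d(volume: float, eps: float, D: float) -> float:
    """Mean first passage time to escape a 3D domain through a small disk.

    Leading-order small-hole asymptotics for an absorbing circular window
    of radius ``eps`` on an otherwise reflecting boundary:

        τ = V / (4 D ε)

    Parameters
    ----------
    volume : μm³
        Domain volume.
    eps : μm
        Radius of the absorbing window.
    D : μm²/s
        Diffusion constant.

    Returns
    -------
    float
        Escape time in seconds.  Scales linearly in the volume and
        inversely in both ``eps`` and ``D``.
    """
    if volume <= 0 or eps <= 0 or D <= 0:
        raise ValueError(
            f"all arguments must be positive (volume={volume}, eps={eps}, D={D})"
        )
    return volume / (4.0 * D * eps)


def mfpt_escape_2d(area: float, absorbing_fraction: float, D: float) -> float:
    """Mean first passage time to escape a 2D domain through a small arc.

    Leading-order (logarithmic) small-hole asymptotics for an absorbing
    boundary arc occupying a fraction ``f`` of the perimeter:

        τ = (A / (π D)) · ln(1/f)

    Diverges logarithmically as f → 0 and decreases monotonically in f.
    Used for surface-receptor motion on a compartmentalized membrane.
    """
    if not 0 < absorbing_fraction < 1:
        raise ValueError(
            f"absorbing fraction must lie in (0, 1), got {absorbing_fraction}"
        )
    if area <= 0 or D <= 0:
        raise ValueError(f"area and D must be positive (area={area}, D={D})")
    return area / (math.pi * D) * math.log(1.0 / absorbing_fraction)
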