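"""Parameter containers for the calcium system, with literature defaults.

Entries whose published values could not be transcribed verbatim carry a
``fill`` flag; every run report embeds the resolved parameter set together
with those flags so no result silently depends on an unflagged guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from ..units import cross_section_area


@dataclass(frozen=True)
class BufferSpec:
    """Immobile (by default) calcium buffer with sequential binding sites.

    The ladder  B·Ca_{j-1} + Ca ⇌ B·Ca_j  (j = 1…n) uses forward rates
    ``k_forward[j-1]`` (1/(μM·s)) and backward rates ``k_backward[j-1]``
    (1/s).  ``diffusion`` defaults to 0 (fixed buffers); the diffusive
    terms are implemented but off.
    """

    name: str
    k_forward: tuple
    k_backward: tuple
    total_concentration: float  # μM
    diffusion: float = 0.0  # μm²/s

    def __post_init__(self) -> None:
        if not 1 <= self.n_sites <= 4:
            raise ValueError(f"supported n_sites is 1..4, got {self.n_sites}")
        if len(self.k_backward) != self.n_sites:
            raise ValueError("k_forward and k_backward lengths differ")
        if min(self.k_forward) <= 0 or min(self.k_backward) <= 0:
            raise ValueError("rates must be positive")
        if self.total_concentration < 0 or self.diffusion < 0:
            raise ValueError("concentration and diffusion must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.k_forward)


@dataclass(frozen=True)
class DyeSpec:
    """Calcium indicator modeled as a single-site buffer."""

    name: str = "Fluo-4"
    k_forward: float = 60.0  # 1/(μM·s)
    k_backward: float = 170.0  # 1/s
    total_concentration: float = 2.0  # μM


@dataclass(frozen=True)
class PumpSpec:
    """Membrane extrusion mechanism with Hill activation.

    Per-length loss rate:  rate_per_pump · surface_density · perimeter ·
    c^h / (K^h + c^h)  ions/(μm·s), where c is the local free-calcium
    concentration (μM).
    """

    name: str
    rate_per_pump: float  # ions/s
    surface_density: float  # 1/μm²
    K_half: float  # μM
    hill: float
    fill: tuple = ()  # names of fields that are literature fills

    def __post_init__(self) -> None:
        if min(self.rate_per_pump, self.surface_density, self.K_half) <= 0:
            raise ValueError("pump parameters must be positive")
        if not 1.0 <= self.hill <= 4.0:
            raise ValueError(f"hill coefficient outside [1, 4]: {self.hill}")


@dataclass(frozen=True)
class SynapseSpec:
    """NMDA-receptor pulse train (difference of two exponentials).

    ``peak_current`` is the peak of each normalized dual-exponential pulse
    (single-channel NMDA current); the calcium entry per unit time is
    I·ca_fraction/(2e), spread uniformly over a footprint of half-width
    ``receptor_radius`` centered at ``position``.
    """

    position: float  # μm
    peak_current: float = 9.0  # pA
    ca_fraction: float = 0.1  # fill (literature ≈ 0.1)
    tau_rise: float = 3e-3  # s
    tau_decay: float = 80e-3  # s
    receptor_radius: float = 0.025  # μm
    frequency: float = 20.0  # Hz
    n_pulses: int = 20
    t0: float = 0.0  # s
    #: cap the summed train at the single-channel current: an already-open
    #: receptor cannot pass more than its open-channel current, which is
    #: what makes the influx (and hence the calcium spread) saturate at
    #: stimulation frequencies above ~1/τ_decay
    saturating: bool = True
    fill: tuple = ("ca_fraction",)

    def __post_init__(self) -> None:
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if not 0 < self.ca_fraction < 1:
            raise ValueError("ca_fraction must lie in (0, 1)")
        if self.frequency <= 0 or self.n_pulses < 1:
            raise ValueError("frequency and n_pulses must be positive")

    @property
    def time_to_peak(self) -> float:
        """Closed-form extremum of the dual exponential (s)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)


@dataclass(frozen=True)
class SpineSinkSpec:
    """Passive spines as perfect calcium absorbers.

    The per-spine absorption rate is the inverse narrow-escape time into
    the neck opening, 1/τ = 4·D·r_neck/V_compartment; the sink acts on a
    footprint of half-width ``neck_radius`` at each position.
    """

    neck_radius: float = 0.1  # μm, Table band 0.05–0.16
    positions: tuple = ()  # μm
    density: float = 0.0  # 1/μm, alternative to explicit positions
    compartment_length: float = 0.313  # μm, calibrated crowding compartment

    def __post_init__(self) -> None:
        if self.neck_radius <= 0:
            raise ValueError("neck radius must be positive")
        if self.density < 0:
            raise ValueError("spine density must be non-negative")


# -- Table defaults ----------------------------------------------------

#: calmodulin: four sequential sites; fast pair (sites 1–2) and slow pair
#: (sites 3–4) with the published rate pairs
CALMODULIN = BufferSpec(
    name="calmodulin",
    k_forward=(160.0, 160.0, 2.3, 2.3),
    k_backward=(405.0, 405.0, 2.4, 2.4),
    total_concentration=25.0,  # medium level; low 10, high 100
)

#: calcineurin: single site
CALCINEURIN = BufferSpec(
    name="calcineurin",
    k_forward=(50.0,),
    k_backward=(25.0,),
    total_concentration=10.0,  # medium level; low 5, high 25
)

FLUO4 = DyeSpec()

#: PMCA: high density, low turnover, non-cooperative
PMCA = PumpSpec(
    name="PMCA",
    rate_per_pump=27.0,  # 0.27e2 ions/s
    surface_density=9200.0,
    K_half=0.45,
    hill=1.0,
    fill=("rate_per_pump", "K_half"),
)

#: NCX: low density, high turnover, cooperative (hill 1.7)
NCX = PumpSpec(
    name="NCX",
    rate_per_pump=4800.0,  # 0.48e4 ions/s
    surface_density=300.0,
    K_half=1.8,
    hill=1.7,
    fill=("rate_per_pump", "K_half"),
)


@dataclass
class ReactionSystemSpec:
    """Complete specification of one calcium reaction-diffusion run."""

    length: float = 20.0  # μm
    dendrite_radius: float = 0.5  # μm
    D_ca: float = 20.0  # μm²/s (crowded); 400 for aqueous
    dx: float = 0.05  # μm
    buffers: tuple = (CALMODULIN, CALCINEURIN)
    dye: DyeSpec | None = FLUO4
    pumps: tuple = (PMCA, NCX)
    spines: SpineSinkSpec | None = None
    synapse: SynapseSpec | None = None
    initial_ca: float = 0.0  # μM, added as a pulse profile by scenarios
    baseline_ca: float = 0.0  # μM resting level
    fill: tuple = ("D_ca",)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.dendrite_radius <= 0 or self.dx <= 0:
            raise ValueError("geometry must be positive")
        if self.D_ca < 0:
            raise ValueError("D_ca must be non-negative")

    @property
    def cross_section(self) -> float:
        return cross_section_area(self.dendrite_radius)

    @property
    def perimeter(self) -> float:
        return 2.0 * math.pi * self.dendrite_radius

    def resolved_parameters(self) -> dict:
        """Full parameter dump with fill flags, for run reports."""

        def tag(obj):
            d = asdict(obj)
            d["_fill_flags"] = list(getattr(obj, "fill", ()) or ())
            return d

        return {
            "length_um": self.length,
            "dendrite_radius_um": self.dendrite_radius,
            "D_ca_um2_s": self.D_ca,
            "dx_um": self.dx,
            "buffers": [asdict(b) for b in self.buffers],
            "dye": asdict(self.dye) if self.dye else None,
            "pumps": [tag(p) for p in self.pumps],
            "spines": asdict(self.spines) if self.spines else None,
            "synapse": tag(self.synapse) if self.synapse else None,
            "initial_ca_uM": self.initial_ca,
            "baseline_ca_uM": self.baseline_ca,
            "system_fill_flags": list(self.fill),
        }
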