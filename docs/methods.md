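# Methods

## The crowding model

Cytoplasmic organelles (mitochondria, ER, spine apparatus, cytoskeleton)
obstruct diffusion along a dendrite. We model the dendrite as a cylinder of
radius a (cross-section S = πa²) partitioned into compartments of length L by
transverse reflecting barriers, each pierced by a small circular opening of
radius ε. Free molecules diffuse with the aqueous constant D inside a
compartment and exchange with neighbors only through the openings.

Starting from the Smoluchowski (overdamped Langevin) description with zero
potential — no force fields act on the inert tracers considered here, so the
potential term is dropped throughout and not exposed as a parameter — the
compartment occupancies N_j obey a master equation whose hop rate is set by
the diffusive conductance of one opening.

### Hop rate: aperture conductance, not one-sided escape

Two related but distinct quantities appear:

- The **one-sided narrow-escape time** τ = V/(4Dε): the mean time to be
  *absorbed* at a disk of radius ε on an otherwise reflecting boundary of a
  compartment of volume V. `mfpt_escape_3d` implements this and the 3D
  Brownian simulator confirms it within ~3–5% at the default geometry.
- The **transmission rate between compartments** k = 2Dε/V. A molecule
  arriving at an open aperture is not "transmitted": the aperture carries an
  access resistance 1/(4Dε) on *each* side, so the inter-compartment
  conductance is 2Dε (Hill's formula), i.e. k = 1/(2τ).

The diffusion limit of the chain with hop length L then gives the effective
1D constant

    D_eff = k L² = (2 ε L / S) · D ,

and the dimensionless **compartment parameter** c = 2εL/S = D_eff/D. We fixed
the prefactor by requiring that the 3D Brownian oracle reproduce D_eff in a
calibrated scene; with the one-sided rate (4Dε/V) the measured apparent D is
exactly half the prediction, with the aperture rate the MSD and line-scan-fit
estimators both agree with D_eff within their particle-bootstrap confidence
intervals (residual deviation ≈ −2%, consistent with the next-order slab and
aperture corrections that the leading-order reduction drops).

### Calibration

c fixes only the product εL. The second condition is an aspect ratio
ε/L = 0.035 (configurable), chosen so that the first-order small-hole
formula stays within its stated ~5% accuracy against the Brownian escape
experiment: we measured a relative error ≈ 0.9·ε/a (5.9% at ε = 0.031 μm,
4.6% at ε = 0.026 μm, 2.6–3.6% at the default ε = 0.0262 μm depending on
seed). Larger ratios (e.g. ε/L = 0.1, implying ε = 0.044 μm) put the formula
error near 8% and were rejected for violating this criterion. With
c = 0.05, a = 0.5 μm the defaults are L ≈ 0.749 μm, ε ≈ 0.0262 μm, matching
the measured twenty-fold slowdown D_cyto/D_water = 1/20 for fluorescein
(D_water = 400 μm²/s → D_eff = 20 μm²/s).

ε/L is bounded by 0.15 (strict by default, warning mode available): beyond
it the small-hole asymptotics degrade.

### Inhomogeneous compartments

For spatially varying ε(x) and V(x) the reduction is the Fick–Jacobs-type
equation ∂t(Vc) = 2DL² ∂x(ε ∂x c), equivalently an Itô process with drift
a(x) = 2DL² ε′(x)/V(x) and diffusion b(x) = 2DL² ε(x)/V(x); the drift
vanishes for constant ε. Profile derivatives are central finite differences
(step 1e-4 μm, configurable on the profile object). The PDE solver is a
conservative finite-volume Crank–Nicolson scheme (default dx = 0.05 μm,
internal step ≈ 0.25 dx²/D), so reflecting-boundary mass conservation holds
to solver precision — a tested invariant.

### Jittered barriers

Almost-periodic media are modeled by independent compartment lengths
l_j = L + σ·η_j with η_j ~ N(0,1) (increments of a unit-variance Brownian
jitter of barrier positions). Taylor-expanding the master equation in the
random positions and averaging gives, to O(σ²), a fourth-order long-wave
equation

    ∂u/∂t = D_jit ∂²u/∂x² + (D_eff σ²/2) ∂⁴u/∂x⁴ ,
    D_jit = D_eff (1 + σ²/L²) ≥ D_eff ,

the σ-independent lattice-discreteness term (L²/12)∂⁴ being dropped in the
continuum limit. Disorder *increases* the apparent diffusion constant; the
periodic equation is recovered at σ = 0 (a tested limit) and the second
moment of the solution grows at 2·D_jit exactly (the ∂⁴ term does not move
the second moment — the moment oracle in the tests). The positive ∂⁴
coefficient makes wavelengths below ≈ 2πσ/√2 formally unstable; they are
outside the validity of the long-wave expansion, so the spectral solver
(cosine basis for reflecting walls, Fourier for periodic) removes those
modes and warns. σ/L is bounded by 0.3.

What D_jit does and does not describe: the σ² enhancement applies to the
*disorder-averaged* density ⟨u⟩ — averaging over barrier realizations
convolves the profile with the distribution of the randomized positions,
which broadens it. The diffusivity measured in any *single* realization is
insensitive to the jitter at O(σ²): the aperture resistances are identical
and the compartment waiting times average to L (a trap-model argument),
and the Brownian simulator confirms that per-realization apparent D stays
at D_eff (within a ~12% envelope set by Monte-Carlo noise plus the ±5%
disorder scatter of a 26-compartment segment). The tests therefore check
the σ→0 limit, the moment oracle and the formula-level σ² ordering, and
check the simulator's per-realization transport against D_eff, not
against D_jit.

### Travel times

First-passage theory on the reduced generator gives, for constant
coefficients with an absorbing soma at 0 and a sealed tip at L_d,
τ(x) = (2 L_d x − x²)/(2 D_eff): 250 s (≈4 min) from the tip of a 100 μm
dendrite at D_eff = 20 μm²/s. The general ε(x), V(x) case is a double
quadrature, checked against the closed form to 1e-9.

## The Brownian simulator

Analytic surfaces (cylinder wall, end caps, barrier disks with circular
holes, a spine assembled from a radial neck cylinder and a head sphere)
replace triangulated meshes: ray/surface intersections are exact, so there
are no mesh discretization artifacts. Steps are Gaussian with per-axis
variance 2D·dt; a segment is traced through up to 128 specular reflections,
with pass-through at hole crossings and interpolated absorption times.

Step-size control distinguishes surface roles:

- Reflecting surfaces are handled exactly for straight segments and do not
  constrain dt (base step 1e-5 s).
- Barrier disks constrain dt through the distance to the nearest plane, with
  a floor (0.4 × hole radius)²/(6D) — fraction configurable in the 0.3–0.5
  band — so that the hole pass/block decision is resolved at the hole scale.
- Absorbing surfaces constrain dt with *no* floor (down to 1e-3 of the
  barrier floor): otherwise the straight-segment tracer misses
  Brownian-bridge crossings and biases first-passage times upward. With this
  rule the absorbing-cap benchmark reproduces the exact 1D first-passage
  answer to ~1% at 4000 walkers.

Each particle carries its own clock; a step that would overshoot the next
sampling tick is clipped onto the tick, which reconciles the asynchronous
adaptive clocks with the line-scan sampling grid (0.7 ms default) without
lag bias. Runs are seeded and bit-reproducible; the sorted-bisection barrier
lookup is an acceleration structure only — brute-force scanning yields
bit-identical trajectories (a tested invariant).

The spine is passive: neck and head reflect (optionally an absorbing head),
particles may re-enter the shaft. Sampling volumes are full-cross-section
disks; a particle inside the spine is outside every sampling volume, which
is what produces the transient concentration drop next to a spine.

Apparent-D estimators: (i) MSD — linear regression of the concentration
profile's second moment, slope = 2·D_app; (ii) fit1d — scalar least squares
of the reduced-1D forward model started from the first recorded frame, D
the only free parameter. The fit compares at the sampling-bin resolution
(0.6 μm) on purpose: the effective equation is valid only above the
compartment scale, and the binned counts of a barrier scene carry a
persistent sub-compartment modulation (bins incommensurate with
compartments) that a finer-resolution forward model would try to damp
diffusively, biasing D down by ~8%; at the bin scale fit1d and MSD agree
to a fraction of a percent. Confidence intervals bootstrap over particles
(the independent units); a time-point bootstrap fallback exists for bare
records and is flagged. Estimation windows discard the early transient
(t_min) where the reduction does not yet hold.

Validation: a bare cylinder with absorbing caps is exactly 1D diffusion
with absorbing ends; the simulator's survival fraction matches the odd-mode
eigenseries (50+ terms) within 2% sup-norm at 1e4 particles, the local
mid-cylinder concentration within 5%, and the mean first passage time
matches L²/(12D) within noise.

## The calcium model

One-dimensional reaction-diffusion on a 20 μm segment (dx = 0.05 μm,
reflecting ends), all species as particles per unit length; concentrations
convert via S·602.214 particles/μm per μM (1 μM ≈ 600 particles/μm³ ≈ 470
particles/μm at d = 1 μm). Components:

- **Buffers** (immobile by default; diffusive terms implemented but off):
  calmodulin as a four-site sequential ladder with rate pairs 160/405 (sites
  1–2) and 2.3/2.4 (sites 3–4) [1/(μM·s), 1/s], total 25 μM (medium; low 10,
  high 100); calcineurin single-site 50/25, total 10 μM (low 5, high 25).
  Occupancy states sum to the total by construction at every node — the
  ladder derivatives cancel exactly.
- **Dye** Fluo-4, single site 60/170, 2 μM, on by default (the experimental
  condition); scenarios may disable it.
- **Pumps** with Hill activation c^h/(K^h + c^h) on the local free-calcium
  concentration, surface densities converted to per-length rates via the
  perimeter πd: PMCA (27 ion/s per pump, 9200/μm², K = 0.45 μM, h = 1.0) and
  NCX (4800 ion/s, 300/μm², K = 1.8 μM, h = 1.7). The pump turnover numbers
  and half-saturations are literature-sourced fills (flagged in every run
  report) because the primary values are not transcribable.
- **Spines** as perfect absorbers with per-spine rate 1/τ = 4·D·r_neck/V
  over one crowding-compartment volume, acting on a footprint of half-width
  r_neck; budget-audited.
- **NMDA input**: dual-exponential pulses (τ_rise 3 ms, τ_decay 80 ms)
  normalized to a 9 pA single-channel peak, calcium fraction 0.1 (fill),
  ions/s = I·f_Ca/(2e), deposited on a 0.05 μm footprint by exact
  cell-overlap weights. The summed train is clipped at the single-channel
  peak: an open receptor cannot exceed its open-channel current. Without the
  cap the influx grows linearly in the stimulation frequency forever and the
  spatial spread never saturates; with it the mean influx saturates once
  pulses overlap (f ≳ 1/τ_decay ≈ 12 Hz), which is what produces the
  documented frequency saturation. The cap is a modeling choice
  (`SynapseSpec.saturating`) and can be disabled.

The method-of-lines system (9 species × 401 nodes for the default scenario)
integrates with BDF and an analytically assembled sparse Jacobian.
Cumulative pump, spine and injection fluxes ride along as quadrature states,
so the calcium budget (free + bound + removed − injected = initial) closes
at solver accuracy — observed ≤1e-12 relative, asserted ≤1e-4. Positivity
holds for all shipped scenarios; halving dx changes the reported spread by
<2%.

**Spread metric**: FWHM of the free-calcium profile by linear interpolation
around the global peak, spread = FWHM/2 measured from the source. Frames
whose peak is below 5% of the trajectory's global peak return NaN — the
width of a signal at the noise floor is not a meaningful spread and no real
line scan would resolve it (without this floor, the 1 Hz maximum would be
set by a residual dome at 0.04% of peak amplitude). Multimodal profiles are
flagged; FWHM is then taken around the global peak only.

Scenarios: pulse relaxation in aqueous (400 μm²/s) vs crowded (20 μm²/s)
solution, bare or with medium buffers + pumps; 1 s NMDA trains at the
segment midpoint; and a 1–100 Hz frequency sweep. With the default (fill)
parameters the sweep gives spreads of ~0.08–0.09 μm, monotone in frequency
and stationary above ~10 Hz — comfortably inside the few-micron microdomain
bound; the absolute spread magnitude depends strongly on the filled pump
parameters, the bound and the saturation behavior do not.

Out of scope (deliberately): calcium stores and CICR waves, voltage
dynamics and the NMDA Mg-block voltage dependence, voltage-gated channels,
back-propagating action potentials, 3D calcium diffusion, mobile-buffer
transport (terms present, default off).

## Synthetic fixtures and the fitter

The fixture generator emulates the uncaging acquisition: Gaussian spot
(σ = 1 μm), line period 0.7 ms, read-out every 0.6 μm, 7–14 replicates
averaged, additive Gaussian noise (default 0.03) on the normalized signal.
The forward model is always the reduced 1D equation — never the 3D
simulator — with the ground truth kept in a sidecar, not in the data file.
What these fixtures do *not* emulate: photobleaching, detector shot noise
(noise is homoscedastic Gaussian), out-of-focus contamination and spot
asphericity; parameter-recovery results therefore bound estimator error
under ideal acquisition, not under all experimental imperfections.

The fitter is scalar least squares over D (log-bounded golden-section), an
overall scale absorbing the arbitrary fluorescence normalization, residual
bootstrap for the CI, and both time-origin conventions (first sample at
uncaging vs one line period later) evaluated — they differ by ~2% at
D = 20 μm²/s and ~8% at 400 μm²/s, and the result reports both when they
disagree by more than 2%. Recovery: within 10% across the crowded (20),
near-spine (27) and aqueous (400 μm²/s) regimes over 20 seeds at noise 0.05.

## Problem sizes in the shipped tests

The test suite scales the Monte-Carlo experiments to 800–4000 walkers and
30–50 ms (confidence intervals widen accordingly); the acceptance script
runs the full 1e4-walker escape experiment and the full six-frequency 1 s
sweep. The 2D escape oracle uses a 3000-walker walk-on-disk simulation; the
travel-time oracle a 1e4-walker lattice walk.

## Known limitations

- The reduction is leading-order in ε: apparent D in barrier scenes sits
  ~2% below 2εLD/S (next-order slab/aperture corrections), and the escape
  formula carries a ~0.9·ε/a relative error.
- The jitter expansion is mean-field to O(σ²); at σ/L → 0.3 the fourth-order
  equation's filtered modes carry a growing share of sharp initial data.
- Masked pump/synapse parameters are literature fills; absolute microdomain
  sizes (not the ≤5 μm bound or the saturation) move with them.
- The spine changes apparent D by less than the Monte-Carlo noise at
  feasible particle counts; the test asserts direction only.
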