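# Methods

## The measurement principle

A soluble macromolecule binding a site buried in a crowded surface layer
pays a steric free-energy penalty ΔU. Adsorption thermodynamics tie that
penalty to the measurable shift of the effective dissociation constant,

    ΔU = kB·T · ln(KD / KD0),

where KD is measured on the crowded surface and KD0 on a bare reference.
Only the ratio matters: sensor chemistry, dye charge, and detector gains
cancel in KD/KD0. The same penalty reads as mechanical work against the
surface layer's osmotic pressure, ΔU ≈ Π·Veff, so Π = kB·T·ln(KD/KD0)/Veff
is a chemistry-agnostic crowding metric. `crowdsense.theory` implements
these relations exactly; the collapse identity ΔU/(Π·Veff) = 1 holds by
construction and is exposed as a self-consistency diagnostic.

The excluded volume Veff of a probe of diameter d is a convention, always
recorded with the result: `sphere_diameter` (π/6)d³, `sphere_radius`
(4π/3)d³, or `cube` d³. The default for IgG-scale estimates is
`sphere_radius`, the generous choice in which the probe also sweeps a
correlation shell of its own radius; with d = 10 nm and KD/KD0 = 20 it
yields 2.9 kPa, inside the 1–4 kPa range such surfaces are expected to
exert. Which convention underlies any particular printed kPa figure is
rarely stated in the literature, so the package treats kPa values as
bound-style estimates, never as calibrations.

Physical constants are CODATA 2018 (kB = 1.380649×10⁻²³ J/K); temperature
is an explicit argument everywhere, default 298 K.

## Brush scaling theory

`theory.brush_insertion_penalty` gives a closed-form estimate of ΔU from an
Alexander–de Gennes brush: height h_b = N·σ·(n·σ²)^(1/3) (N beads of
diameter σ per chain, grafting density n converted to per-σ² units), monomer
volume fraction φ = (n·σ²)^(2/3), semidilute osmotic pressure
Π_b = (kBT/σ³)·φ^(9/4), and ΔU = Π_b·V_overlap with V_overlap the
spherical-cap volume of the probe below z = h_b when the probe sits at
contact (centre z = σs/2). This is deliberately the simplest standard
scaling form: it is monotone nondecreasing in n, N, σ, and σs and
reproduces the qualitative ordering of simulated brushes, but it is flat in
N once the probe is fully submerged (φ does not depend on N) and carries no
electrostatics — charge effects live in the simulator only. It should be
read as a replaceable baseline curve, not a quantitative fit.

## The coarse-grained simulator

`crowdsense.simulate` integrates overdamped (Brownian) Langevin dynamics of
Kremer–Grest bead-spring chains grafted to a flat, non-deforming wall:

* FENE bonds, k = 30 kBT/σ², R0 = 1.5 σ; WCA repulsion, ε = 1 kBT, cutoff
  2^(1/6) σ, applied to all bead pairs; a WCA-form wall in z (σ_wall = σ/2)
  on every bead.
* Anchors are constrained to the z = σ/2 plane but diffuse laterally with
  the same friction as other beads (membrane proteins are mobile); a
  quenched-anchor mode exists for oracle tests.
* Optional cosine bending U = k_b(1 − cos φ) between successive bond
  vectors (zero when straight). The default is fully flexible (k_b = 0);
  2 kBT is the semiflexible setting. The cosine form is used instead of a
  harmonic angle because it is the standard Kremer–Grest semiflexible term
  with the same stiffness scale and a simpler force.
* Optional Yukawa (screened-Coulomb) pair repulsion
  U(r) = A·(σ/r)·exp(−κ(r−σ)), default amplitude A = 2 kBT, cutoff where
  U < 10⁻³ kBT. Charged-brush results are sensitive to A, which is not
  independently calibrated here, so all charged-brush claims are tested
  directionally (charged > uncharged; height increasing with Debye length),
  never as absolute swelling percentages.

Reduced units: σ = 1, kBT = 1, friction γ = 1, so τ = σ²γ/kBT is the bead
diffusion time. The integrator is first-order Euler–Maruyama with
Δt = 10⁻⁴ τ (the enforced stability bound; a FENE bond reaching R0 raises an
integration error naming the step and chain rather than silently clamping).
Equilibrium observables are integrator-independent, which is why a simple
first-order scheme suffices. Trajectories are bit-reproducible: every
integration block draws its RNG stream from the config seed and a block
counter.

Initial states stand chains up as jittered vertical rods on
rejection-sampled anchor sites (minimum lateral separation 0.9 σ) so that no
two chains start overlapped; at near-jammed densities the farthest candidate
found is accepted instead.

Preset coarse-grainings: a 4-nm bead per structured protein domain
(engineered FNIII-repeat surfaces); PEG3k as N = 5 beads of σ = 1.2 nm
(contour 6 nm, roughly twice the Flory radius).

## Probe free energies: Widom insertion

Rather than simulating a bound probe explicitly, the probe's steric free
energy U(z) is estimated by Widom test-particle insertion into equilibrated
frames: U(z) = −kBT·ln⟨exp(−βΔE)⟩ over seeded uniform xy insertions. For
the default hard-sphere probe this is −ln(non-overlap fraction) with a
binomial/delta-method standard error per bin; a soft (WCA, ε = 1 kBT) probe
mode exists. The two estimators are equal in expectation to explicit-probe
sampling but orders of magnitude cheaper at desk scale. Bins where every
insertion overlapped report U = ∞ and are flagged, never dropped.

Because the bare-surface well depth cancels in ΔU = U_crowded − U_bare,
profiles are steric-only and the affinity shift is read at the binding
height z_b = σs/2 (probe touching the wall) by default; z_b is an explicit
argument. Standard errors combine in quadrature. Whether real probes see
crowders as hard or soft spheres is not settled; hard-core is the default
and the directional conclusions do not depend on the choice.

Brush density profiles are plain z-histograms (conservation is exact by
construction); the brush height is the first moment, with a standard error
from frame-to-frame variation of per-frame mean heights.

## The flow-cytometry pipeline

Event tables carry one row per cell per bulk concentration with an anchor
(FITC) channel and a probe/antibody channel. The pipeline:

1. **Gating** — drop events with anchor intensity below
   max(floor, 1st percentile) or above the 99.9th percentile; all gates and
   counts are reported. (Instrument gating in real experiments is implicit;
   these defaults are configurable.)
2. **Normalization** — per-event signal = probe/anchor. Both channels scale
   with the per-cell saturation signal Cmax (cell size, anchor density), so
   the division cancels cell-to-cell size variation; any global channel
   gain also cancels, and ratios are invariant to detector rescaling.
3. **Isotherms** — group by concentration: means, SD/√n standard errors,
   event counts.
4. **Low-concentration slope** — weighted least squares through the origin
   over points with mean coverage θ̄ below a cutoff (default 0.2, at which
   the Langmuir linearization bias is <11% and shrinking as C → 0). The
   weights are 1/C²: with multiplicative detection noise the group-mean SD
   is proportional to θ̄ ≈ C/KD, making 1/C² the inverse-variance choice;
   it also concentrates weight at the lowest concentrations where the
   linearization is most accurate. Algebraically the estimator is the mean
   of per-point ratios θ̄/C. Uncertainty comes from a seeded bootstrap over
   events (default 1,000 resamples).
5. **Slope ratio** — KD/KD0 = slope_reference/slope_sample. The
   low-concentration slope of θ ≈ C/KD is 1/KD, so the crowded surface's
   smaller slope puts the ratio above 1. (The opposite orientation
   sometimes appears in print; this package fixes the orientation from the
   definitions and documents it rather than matching formula typography.)
6. **Full Langmuir fit** — nonlinear least squares of Cmax·C/(C+KD) as a
   cross-check; a fitted KD outside the measured concentration range by
   more than 100× is flagged ill-posed. Slope-ratio and full-fit ratios
   agree within ~10% whenever the low-concentration points sit below half
   saturation.
7. **Single-cell crowding** — at one fixed low concentration,
   r_i = (reference mean normalized signal)/(cell i's normalized signal)
   ≈ KD_i/KD_ref. Zero-signal cells are excluded and counted. Population
   summaries: mean, SD, CV = SD/mean, median, quartiles. Expression-binned
   curves use log10-spaced bins (default 20) with a minimum-count flag
   (default 10 cells).
8. **Group comparison** — one-way ANOVA plus Tukey HSD with the usual
   significance bands (n.s., <0.05, <0.01, <0.001), on replicate-level
   means.

Intensity units are arbitrary throughout; no molecule-equivalent
(MESF) calibration is performed because every reported quantity is a ratio
in which the conversion cancels.

## Surface-height analysis

The height module is the arithmetic layer of cell-surface optical
profilometry: ⟨h⟩ = mean(h_measured) − ⟨h_offset⟩, where the offset comes
from a baseline calibration on a membrane-proximal sensor pair and is
averaged per population (matching the ⟨h_offset⟩ notation; per-cell offset
pairing is not assumed). Sample and calibration standard errors combine in
quadrature as independent noise sources. QC-flagged cells (nonspherical,
tubulated, budding) are excluded before averaging and counted. Adding any
constant to both channels leaves ⟨h⟩ exactly unchanged. Image processing,
equatorial radius fitting, and PSF modelling are out of scope — the module
consumes per-cell height tables.

## Synthetic data: what it emulates, and what it does not

Generators produce every input the analyses consume, fully seeded:

* **Isotherm events** — per-cell Cmax lognormal (CV 25% default), anchor
  channel proportional to Cmax, probe channel Langmuir-bound
  (Cmax·C/(C+KD)) with independent multiplicative lognormal detection noise
  per channel (CV 10%) and additive Gaussian background (SD 1% of the
  median noiseless signal). Reference sample at KD0, crowded at KD0·ratio.
  The default concentration grid {0.05, 0.1, 0.25, 0.5, 1, 2} nM spans well
  below a 10 nM reference KD. Noise magnitudes are declared assumptions
  chosen to resemble typical cytometer event dispersion, not fits to any
  instrument.
* **Populations** — per-cell KD/KD0 lognormal with a specified geometric
  mean and CV; optional expression channel spanning ≥2 decades with a
  monotone crowding-energy map ΔU(expression).
* **Height tables** — true height + offset + Gaussian noise, with a
  binomial fraction of QC-flagged defect cells, plus a matching calibration
  table.
* **Scenario presets** — named parameter sets for the studied surfaces
  (bare bead, PEG3k at 15,000/µm², 1/3/5-domain engineered proteins at
  10,000/µm², sialylated/desialylated mucin-like surfaces, red-cell-like
  and tumor-cell-like populations). The multidomain presets carry 2.0 as a
  lower-bound effect size.

What the generators deliberately omit: spectral spillover and compensation,
doublets, acquisition-time drift, instrument electronics, and any
height-dependence of crowding. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise structure
— not robustness to every artefact of real cytometry.

Two-channel units are generated so that the anchor channel reports the
saturation signal in probe-equivalent units (probe/anchor ≈ θ); this is the
situation the anchor-quench calibration establishes in the real assay, and
it is what makes a coverage cutoff on the normalized signal meaningful.

## Bivalent antibodies

IgG sensors have two binding constants. The package reduces the full
surface-avidity model to a single-parameter correction
K_eff = KD1/(1 + ρ/K2_2D), with ρ the antigen surface density and K2_2D the
2D crosslinking scale (default 14,000/µm², placing a 10% avidity deviation
at ρ = 1,400/µm²). Below that density the sensor is effectively monovalent
and the measurement is insensitive to the exact anchor density — the regime
in which the two-channel assay is designed to operate. The full
two-constant model is out of scope.

## Problem sizes and numerical choices

* The simulated multidomain-brush measurement runs 100 mobile-anchor chains
  in a 100×100 nm periodic box, 10⁵ equilibration steps (10 τ) and 100
  frames at 0.2 τ spacing, with 10⁶ insertions per height — sizes chosen so
  the full protocol completes in minutes on one CPU while leaving the
  directional and fold-change conclusions many standard errors clear of
  their thresholds.
* In-suite directional tests use 40–50 nm boxes, 24–25 chains, and 30–40
  frames; comparisons are made at 2–3 measured standard errors.
* Pipeline recoveries use 20,000 events per concentration and 5,000-cell
  populations, the scale of a routine cytometry acquisition.
* Slope bootstrap: 1,000 resamples, chunked to bound memory.
* Tie-breaks and degenerate inputs: zero-density brushes return ΔU = 0
  exactly; empty insertion bins return ∞ flagged; single-measurement
  calibrations return an undefined (NaN) SE and a flag; all-gated-out event
  tables raise with gate diagnostics.

## Known limitations

* The brush scaling curve is a baseline, not a fitted theory; its absolute
  ΔU values should not be compared quantitatively to simulation output.
* Charged-brush amplitudes (Yukawa A) are uncalibrated; only directions are
  claimed.
* The slope-ratio estimator retains a small negative linearization bias
  (≈5–8% at the default grids) that shrinks as the grid moves below KD;
  the full Langmuir fit is bias-free on exact data and is the recommended
  cross-check when the grid reaches half-saturation.
* Single-cell ratios divide by per-cell signal, so the estimator is biased
  upward by roughly (1 + CV²_detection) and breaks down for cells whose
  signal approaches the background floor; such cells are excluded and
  counted rather than imputed.
* No hydrodynamic interactions, membrane deformation, explicit ions,
  binding kinetics, or explicit solvent anywhere in the simulator.
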