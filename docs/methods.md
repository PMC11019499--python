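# Methods

This note documents the models implemented in `lamella`, the synthetic-data
generator that stands in for beamline data and coarse-grained MD
trajectories, the numerical choices, and what the tests do and do not
establish.

## Scope and units

Coordinates are nanometres, scattering vectors nm⁻¹, times seconds,
concentrations volume percent.  Boxes are orthorhombic with the lamellar
stacking normal along z; all z arithmetic uses the minimum-image convention
and beads are wrapped into the primary box before histogramming.  File
formats are GRO-style fixed columns for configurations (1-based ids on
disk, 0-based in memory; multi-frame by concatenation) and plain ASCII
columns for scattering profiles.

## SAXS Bragg analysis

A lamellar stack of repeat *d* produces Bragg orders at *q₍ₙ₎* = 2πn/d.
The pipeline is:

1. **Background.** A three-parameter model a·q⁻ᵇ + c is fitted by iterative
   masking: fit, drop points more than 2 robust sd above the fit (on the
   variance-stabilised residual, see below), refit; six rounds or until the
   mask stabilises.  A power law plus constant is the simplest shape that
   tracks both the low-q upturn and the flat incoherent floor of a
   dilute-vesicle profile; the experiment's own background treatment is
   generally instrument-specific, so the model is a package choice.
2. **Detection.** The residual (raw minus background) is smoothed with a
   moving-average window (default 5 points) and divided by √background,
   since counting noise grows with intensity; on that variance-stabilised
   series a peak must clear `prominence_factor` (default 5) times the
   robust noise sd *and* a relative floor (`min_rel_prominence`·√background,
   default 0.005).  Prominence is evaluated in a local window (about twice
   the Gaussian refinement half-width) so slow baseline drift cannot
   accumulate into a fake peak, and the peak height itself must clear the
   same threshold.  A value exactly at threshold counts as a peak — the
   boundary policy is deterministic.
3. **Refinement.** Each surviving maximum is refined by a local Gaussian
   fit (center, amplitude, width) on the unscaled residual within
   ±0.12 nm⁻¹; if the fit fails the raw sample is kept.
4. **Order assignment and d.**  Orders are the nearest integer to
   q/q₁ with a 15% relative tolerance — wide enough to keep slightly
   anharmonic triplets such as ratios 1 : 1.99 : 3.03 — and duplicates keep
   the candidate closest to its harmonic position.  The repeat distance is
   an origin-constrained least-squares fit, slope = Σn·qₙ/Σn²,
   d = 2π/slope; a single order gives d = 2π/q₁ exactly.  Unassignable
   peaks are reported but excluded.  d is shown to 0.1 nm in user-facing
   output; full precision is kept internally.
5. **Lamellarity.** A profile is multilamellar iff at least one Bragg order
   is detected; the peak list and background fit are returned as evidence.
   The hydration-layer helper returns d minus a bilayer thickness, flagging
   thin (< 0.5 nm) and negative results rather than rejecting them.
6. **Time series.** Each profile of a contact-time series runs the same
   pipeline; times must be unique, entries without peaks carry an undefined
   d, and the series reports the reduction of d between its first and last
   defined entries.

## Trajectory metrics

* **Structure factor.** F(q) = Σₖ fₖ·exp(i q zₖ) with fₖ = 1 unless
  overridden, intensity ⟨|F|²⟩·P averaged over frames, on the
  periodicity-compatible grid q = 2πm/L_z only — off-grid q would break
  periodic-image consistency and is rejected naming the valid grid.  The
  polarization factor P is a pluggable scalar defaulting to 1 (small-angle
  limit).  Only the lamellar-normal factor is computed; there is no powder
  averaging.
* **Density profiles.** Frame-averaged, box-wrapped histograms per bead
  type or residue name, in nm⁻³; the integral times the box cross-section
  reproduces mean bead counts (a conservation test).  With leaflet
  splitting, lipid beads inherit their lipid's current leaflet label.
* **Area per lipid.** A = Lx·Ly/(N_lipids/2n_b): purely geometric, with the
  frame-to-frame standard deviation as the uncertainty.  (The ± numbers
  throughout are sd, and labelled as such.)
* **Leaflet assignment.** Phosphate z values are clustered into 2n_b planes
  by cutting the circular sorted sequence at its largest gaps; the smallest
  separating gap must exceed `min_plane_gap` (default 0.5 nm) or the
  routine fails with the gap spectrum as diagnostics.  Planes are paired
  into bilayers by the tail direction of their lipids (tails point to the
  midplane), which disambiguates the pairing even when the water gap is
  narrower than the membrane.  This is adequate for flat lamellae and
  unsuitable for vesicles, which have no global normal.
* **d_PP.** Per bilayer, the circular-mean phosphate z of the upper leaflet
  minus the lower, minimum-image along z; a collapsed bilayer (d_PP below
  0.05 nm) is flagged degenerate rather than rejected.
* **Segmental order.** S_b = ⟨(3cos²ϑ_b − 1)/2⟩ per bond over lipids and
  frames, palmitoyl and oleoyl chains separately, bonds numbered from the
  ester anchor (bond 1 = EST→segment 2) to the terminal CT2.
* **Chain angles.** cos θ of the EST→CT2 vector of each chain, signs
  preserved, as a probability histogram.  As the width statistic the
  distribution exposes `alignment_spread` = ⟨(1 − |cos θ|)²⟩, the second
  moment about the aligned peaks at cos θ = ±1: it is zero for a perfectly
  ordered stack and grows monotonically as orientations randomise, which
  makes it the right monotone surrogate for "the angular distribution
  widens".  (The plain variance of |cos θ| is not monotone under the
  generator's aligned/isotropic mixture and is reported only as
  `variance`.)
* **Flip-flops.** An event is a lipid whose (bilayer, leaflet) label
  changes between consecutive frames and keeps the new label for at least
  `persistence` frames (default 2) or to the end of the trajectory; the
  persistence requirement suppresses boundary flicker.
* **Ethanol penetration.** The mean ETNL density within |z − midplane| <
  0.25·d_PP divided by its mean density in the solvent slabs (beyond the
  head zone); zero when no ethanol is present, an error when the solvent
  contains none (ratio undefined).
* **Analysis window.** Trajectory summaries accept a tail fraction so only
  the late, equilibrated part of a trajectory enters the averages; the
  synthetic trajectories are stationary, so tests use the whole window.

## The synthetic-data generator

`LamellarSpec` plants the observables the metrics must recover: n_bilayers,
lipids per leaflet, area per lipid A, phosphate–phosphate thickness d_PP,
repeat d, segmental order target S, ethanol vol% with a membrane partition
fraction, flip-flop count, anchor jitter, and a seed.  Defaults are the
water-only reference condition: three bilayers, d = 6.1 nm, d_PP = 3.85 nm,
A = 0.647 nm², S = 0.35 (a typical coarse-grained POPC plateau value),
jitter 0.05 nm, 100 lipids per leaflet.

Construction: L_z = n_b·d with bilayer midplanes at (i+½)d, Lx·Ly =
lipids_per_leaflet·A, lipid anchors on a jittered square lattice, phosphate
planes at ±d_PP/2 per bilayer.  Head beads (NC, PH, GL) stack along the
outward normal; each chain starts at its ester anchor and grows inward with
0.42 nm bonds whose directions are drawn from a mixture tuned to the
planted order: with probability p a bond lies exactly along the normal
(order 1; for negative targets, exactly in-plane, order −½), otherwise its
cosine is uniform — over the inward hemisphere by default, so tails
progress toward and across the midplane as real tails do, or over the full
sphere when `chain_inward_bias` is off.  Both random components have order
exactly 0 (the cos² law is the same), so the planted S is p (or −p/2).
The bond spacing and the hemisphere bias were chosen so the stack's bead
density is slab-like: with a tighter, head-heavy geometry the f_k = 1
structure factor's first order nearly cancels against the solvent slab and
higher harmonics dominate, which no lamellar SAXS measurement shows.

Solvent fills the region outside |z − midplane| < d_PP/2 uniformly at the
bulk-water bead density (33.4 molecules nm⁻³, three waters per WAT bead) —
uniform placement rather than a lattice because the requested ethanol
fraction fixes integer bead counts a lattice cannot hit, and no analysis
stage requires physical packing; there is no excluded volume anywhere.
Ethanol beads (one molecule each) replace water beads to match the
requested vol% via molar volumes (water 18.07, ethanol 58.5 cm³ mol⁻¹,
overridable — the conversion convention is an assumption, stated here
because the underlying studies do not print theirs).  A configurable
fraction of ETNL beads is placed inside membrane cores to emulate deep
ethanol penetration; there are no energetics.  Flip-flopped lipids are
planted statically with their head across the midplane (geometry generated
as a member of the opposite leaflet); in trajectories the flip switches on
at a chosen frame.  Identical spec and seed give bit-identical output.

SAXS profiles are Gaussian orders at 2πn/d — or at explicit centers, for
anharmonic fixtures — over an a·q⁻ᵇ + c background on a 0.1–4.0 nm⁻¹ grid,
with Poisson counting noise at a configurable intensity-per-count scale
(default 0.05; 0 disables noise and the per-point σ column).

What the generator does **not** emulate: thermal undulations and
correlated roughness, realistic bead packing and excluded volume, chain
conformational statistics beyond the planted order parameter, form-factor
effects of vesicle curvature, and any dynamics — flip-flops are planted,
not diffusive.  Passing recovery tests therefore demonstrates that the
estimators are unbiased on geometry with known ground truth and stated
noise, not that they are robust to every artifact of real trajectories.

## Mixing model

The channel is 1 mm × 0.7 mm with 50 µL/min total flow and a side:center
flow-rate ratio (FRR) of 5; side streams are pure ethanol by default.  The
fully mixed fraction c_stock·FRR/(FRR+1) and the residence-time map
t = x/u, u = Q/(width·depth), are exact bookkeeping, independent of the
velocity profile.  Cross-channel homogenisation is modelled as steady
plug-flow advection with transverse diffusion, ∂c/∂x = (D/u)·∂²c/∂y², with
no-flux walls and a step inlet whose center stream occupies 1/(FRR+1) of
the width (equal-depth volumetric partition; the true inlet width under
unequal viscosities is not modelled).  The explicit march enforces the
diffusive stability bound Δx ≤ Δy²u/2D and conserves the cross-channel
mean to machine precision, approaching the mixed fraction downstream.
D defaults to 1.2×10⁻⁹ m²/s (ethanol in water, configurable).  This 2-D
plug-flow model reproduces the dilution endpoint and residence times
exactly and the cross-channel maps only qualitatively — no Navier–Stokes
solve, no 3-D geometry, no depth dependence.  A Reynolds-number helper
(hydraulic diameter, water-like properties) is provided for orientation
only, since the result depends entirely on those assumptions.

## Numerical choices and degenerate inputs

Duplicate q rows in profile files are merged by averaging; negative
intensities are clamped to zero with a warning (configurable to reject).
Peak detection requires at least 50 points; leaflet assignment requires at
least as many lipids as leaflets; the density histogram requires ≥10 bins;
the advection–diffusion grid ≥50 cells.  Ties at detection thresholds count
as peaks.  Zero-length bond vectors, empty selections, inconsistent plane
counts, off-grid q, duplicate contact times and an x beyond the simulated
channel all raise validation errors that name the offending quantity.

## Test sizes

The suite runs on small fixtures chosen for statistical headroom rather
than realism: stacks of 3 bilayers × 50–100 lipids per leaflet, 4–17
frames (the isotropic-order check uses ≥10⁴ bond samples), 1000-point
profiles, and a 120-cell channel grid.  All planted-parameter recovery
tolerances (2% for A, d_PP, S; 1%/3% for noiseless/noisy d) are asserted at
these sizes with fixed seeds.
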