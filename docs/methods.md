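# Methods

## Signal model

A TCSPC FLIM acquisition records, per pixel, a histogram of photon arrival
times relative to the laser pulse.  We model the NAD(P)H decay at a pixel
as a two-species mixture: free NAD(P)H with lifetime τ_free and
enzyme-bound NAD(P)H with lifetime τ_bound > τ_free.  The parameter
α ∈ [0, 1] is the **bound intensity fraction** — the expected share of
collected photons emitted by the bound species.  The expected content of
bin k (center t_k, 256 bins tiling one laser period) is

    E[I_k] = N · [ (1 − α) F̂_k + α B̂_k ],

where F̂ and B̂ are the unit-sum sampled mono-exponentials and N the
expected photon count.  Measured histograms draw each bin independently
from a Poisson distribution with that mean.  Because α is an intensity
fraction, the pixel's phasor is exactly the intensity-weighted average of
the two pure-species phasors, i.e. it lies on the chord between them at
fractional distance α from the free end — the property that makes the
fraction-bound statistic linear in α.

No instrument-response convolution is applied in the simulator: the
analysis never deconvolves an IRF either, and first-harmonic calibration
against a known standard absorbs the instrument's phase delay and
modulation loss, which is how the workflow treats the real system.

## Phasor transform and conventions

g and s are the normalized first Fourier cosine/sine moments of the
histogram evaluated at ω = 2πf with bin-center timestamps (plain sums;
equivalent to the first FFT coefficient up to the bin-center phase
convention, which the calibration round trip covers).  Only the first
harmonic is used.  Pixels with zero total count carry an explicit
invalid flag — no sentinel values.  Useful identities:

- mono-exponential: g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) (universal
  semicircle, s² = g(1−g));
- phase lifetime TauP = (s/g)/ω; modulation lifetime
  TauM = sqrt(1/(g²+s²) − 1)/ω; TauP = TauM only for mono-exponential
  decays, TauP < TauM inside the semicircle.  Pixels with g ≤ 0 or
  g² + s² ≥ 1 are masked invalid rather than raising.

With 256 bins at 80 MHz, the discrete transform recovers TauP from a
noiseless mono-exponential to 0.006% at 4.04 ns and 0.13% at 0.4 ns (the
truncation of the decay at one period cancels exactly between numerator
and denominator; the residual error is pure discretization).

## Calibration

A mono-exponential standard of known lifetime — fluorescein at pH 9,
taken as 4.04 ns — is measured (or simulated), and the fitted transform
is phase_offset = measured phase − analytic phase, modulation_factor =
measured modulus / analytic modulus.  Calibrating an image rotates each
pixel's phasor by −phase_offset and scales it by 1/modulation_factor;
re-calibrating an already-calibrated image is refused.  In `analytic`
reference mode the standard is simulated noiselessly under the same
binning, so the fitted transform also absorbs the discretization bias of
the transform itself.  The source text gives the fluorescein lifetime
both as 4.04 ns and as 4 ns in different sections; 4.04 is the default
and the value is configurable.  Physical instrument response can only
reduce modulation, so simulated instrument shifts accept modulation
factors in (0, 1] (implemented as a uniform background pedestal, which
scales the first-harmonic modulus without touching the phase).

## Fraction of bound NAD(P)H

f_bound = sqrt((g − g_f)² + (s − s_f)²), the raw Euclidean distance from
a pixel's calibrated phasor to the free-NAD(P)H location (0.4 ns placed
analytically on the semicircle).  The distance is deliberately **not**
normalized: the bound-species location is not assumed, because the bound
lifetime depends on the binding enzyme.  Consequently f_bound has
phasor-plane units; for a known two-species simulation it equals
α × (chord length to the bound location), which the recovery tests use to
convert back to α.  Pixels are valid only where total photons are
strictly greater than the threshold (default 5 photons — strict ">", so a
pixel at exactly 5 counts is excluded) and the phasor is defined.

Averaging order: per-cell statistics average per-pixel f_bound over the
mask (not the distance of the averaged phasor).  For homogeneous regions
the two orders agree to < 0.01; for heterogeneous regions they differ
because the distance is a convex function of (g, s) — pixel-averaging is
the documented choice.

## Segmentation

Masks are built once per field on a maximum-intensity Z-projection of the
marker channel when present, else of the NAD(P)H intensity: Gaussian blur
(default σ = 2 px) → global threshold (Otsu by default; fixed value
available) → binary hole filling → 4-connected components → removal of
objects below min_area (default 50 px) → optional border exclusion.
Hole filling is included because cortical markers image as rings and
threshold-only ring masks are annuli.  Labels are renumbered in row-major
centroid order, so identical inputs give identical label images.  The
same 2-D mask is reused at every Z plane; per-plane validity is handled
by the photon threshold, not by per-plane masks.  Touching cells are not
split (no watershed).  Blur, threshold rule, minimum size and border
policy are analysis parameters, not measured constants; σ should scale
with cell size (the test configuration uses σ = 1 px for ~4.5 px-radius
phantom cells, against σ = 2 px for the ~10 px default).  Cells whose
mean viability-channel signal exceeds a cutoff are removed before
quantification.  Timepoint linking is greedy nearest-centroid matching
with a maximum displacement radius; unmatched cells open fresh
identities and lost tracks are never reused.

## Per-cell quantification

For each cell and plane, the mean f_bound over pixels that are in-mask
AND valid; a plane with no valid pixel is explicit missing data (NaN),
never zero.  The volume mean pools all valid in-mask voxels — a
valid-pixel-count-weighted mean of the per-Z means — because the cell
average is defined over the pixels above threshold in the entire volume.
Cell area is mask pixel count × pixel_size²; Z offsets are
(index + 1) × z_step with index 0 the coverslip-proximal (immune-synapse)
plane, so the default 6 planes at 3 µm sit at 3–18 µm.  (The source text
states both a 3 µm and a 0.3 µm Z step in different sections; 3 µm is the
default, consistent with its axial-profile axis labels.)

## Group statistics

- Cell level: two-sided Welch t-test on volume-mean f_bound, medians and
  IQR reported.  "Welch" is chosen for unpaired contrasts because group
  variances are not assumed equal.
- Donor level: cells collapse to per-donor means, then a paired two-sided
  t-test across donors.
- Axial: per-plane Welch tests between conditions; within-condition
  bottom-vs-top contrasts pair the same cells at the two planes.
- Area coupling: Pearson r (Spearman as companion) between area and
  volume-mean f_bound, per condition and pooled; groups with n < 3 or
  zero variance report NaN.
- Raw per-comparison p-values by default (Holm correction available
  behind a flag); significance tiers are * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001.

Label permutation leaves the cell-level test uniform (checked by KS test
against uniform over 1000 permutations), and the null rejection rate at
α = 0.05 is calibrated (3–5% over 400 simulated null experiments).

## The synthetic-data generator

The phantom emulates fields of T cells spread on a coated coverslip:

- geometry: n disk cells (default 10, radius 10 px ± 15% uniform jitter,
  non-overlapping placement with a minimum gap, largest-first sequential
  packing with a retry budget, error on jamming); one 2-D footprint per
  cell shared by all Z planes;
- compartments: nuclear core (radius fraction 0.55) with α = 0.25 and
  0.35× photon budget (nuclei are dim — their NAD(P)H/NAD+ ratio is far
  lower than mitochondria's); cytoplasm α = 0.40; mitochondrial puncta
  α = 0.70 with 1.5× photons.  Every cell is a scaled copy of one
  template — puncta count is size-independent while punctum radius and
  placement scale with the cell radius — so compartment composition, and
  hence truth α, is independent of cell size by construction (anything
  else silently couples size to metabolic state and biases the
  area-correlation null);
- photons: uniform 200–300 expected photons per in-cell pixel (before
  compartment brightness factors), background 1 photon; independent
  Poisson counts per time bin;
- axial structure: puncta counts per plane follow a U-shaped weight
  profile (mitochondria concentrate at the bottom and top of spread
  cells); a synapse_bias parameter additionally enriches bottom planes
  in the activated condition;
- condition effect: "activated" adds condition_effect (default −0.1, the
  glycolytic shift) to every compartment's α.  Rendering the same seed
  under both conditions reuses identical geometry, so the ground-truth
  per-cell difference is exactly the condition effect;
- area coupling: each cell's α shifts by
  area_coupling × (area − πr₀²)/πr₀² with r₀ the nominal radius,
  centered on the nominal (not the realized field-mean) area so shifts
  are independent across cells.  The default is −0.1, the same magnitude
  as the activation effect, because spreading is the activated
  phenotype — the area–metabolism association mirrors the activation
  shift;
- companion channels: a bright cortical marker ring (LifeAct-like) with
  dim interior for mask building, and a viability channel in which a
  configurable fraction of "dead" cells (α shifted by −0.15) is
  uniformly elevated;
- reproducibility: one master seed fans out via SeedSequence spawning to
  independent child streams (geometry, puncta, photon budgets, shot
  noise, channels), so every stochastic operation is replayable.

Lifetimes default to τ_free = 0.4 ns and τ_bound = 3.2 ns.  No bound
lifetime is published for this system ("bound" is enzyme-dependent);
3.2 ns sits inside the range reported for protein-bound NAD(P)H and is
configurable — nothing in the analysis depends on its exact value, since
the statistic never assumes a bound location.

What the generator does **not** emulate — and therefore what passing
recovery tests do not establish for real data: optical blur (PSF),
detector afterpulsing and pile-up, instrument-response convolution,
autofluorescence background from other fluorophores, cell motion within
an acquisition, mitosis, and genuinely 3-D cell shapes (cells are
columns; real cells narrow at top and bottom, which the shared-2-D-mask
rule handles via the photon threshold).

## Numerical choices and degenerate inputs

- Bin centers (k + 1/2)Δ; period stored explicitly in metadata.
- Zero-count pixels, sub-threshold pixels and unphysical phasors carry
  validity flags; aggregation treats empty cell-planes as missing.
- Calibration refuses a zero-modulus reference; config loading rejects
  unknown keys and reports the offending block for invalid values.
- Identical groups give t = 0, p = 1 (the bottom-vs-top paired test
  short-circuits exactly identical pairs rather than dividing by a zero
  variance estimate).
- All randomness flows through numpy Generators seeded explicitly;
  pipeline stage seeds derive from the run seed by documented spawning.

## Problem sizes in the test suite

Unit tests run on single histograms or ≤ 64×64 frames.  End-to-end
statistical checks (activation-effect power over 100 runs, null
rejection rate over 400 runs, area-coupling sign recovery over 200 runs)
run the full pipeline at a reduced scale chosen to keep the suite fast
while preserving the study conditions that matter: 50 cells per
condition, 6 Z planes, the −0.1 activation effect, 200–300 photons per
pixel — with 128×128 frames, 64 time bins, 4.5 px cell radius, and blur
scaled accordingly.  Segmentation-recovery and axial-profile checks use
the full-scale defaults (256×256, 256 bins).

## Known limitations

- The fraction-bound statistic is a distance, not a normalized fraction;
  values are comparable across cells and conditions at fixed ω and
  reference, but not across instruments without recalibration.
- Threshold + connected components cannot separate touching cells;
  dense fields need the marker channel and adequate spacing (a watershed
  extension point exists but is off by default).
- Donor-level inference assumes donors are exchangeable and effects
  homogeneous; no mixed-effects modelling is attempted.
- The viability filter is a mean-intensity cutoff; partial dye uptake or
  segmentation bleed between neighbours can misclassify cells.
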