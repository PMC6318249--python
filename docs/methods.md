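# Methods

This note documents the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic-data
tests do and do not demonstrate about real instrument data.

## Scope and data model

The package covers the computational half of a native IM-MS study of a
homodimeric DNA-binding protein: species quantification from native
spectra, travelling-wave IMS CCS calibration, titration-based K_D
determination, collision-induced unfolding (CIU) analysis, and
hard-sphere theoretical CCS from atomic coordinates. Instrument
acquisition, LC-MS/MS phosphosite mapping and molecular-dynamics
simulation are out of scope; the CCS engines consume coordinates such
simulations produce (PDB/XYZ).

Five containers carry the data: `MassSpectrum` (m/z, intensity),
`CCSDistribution` (CCS, intensity, charge, calibration),
`TitrationSeries` ([P]₀ plus ([L]₀, ratio) points), `CIUFingerprint`
(intensity over collision voltage × mobility), and `AtomicStructure`
(elements, coordinates, collision radii). All masses are Da, m/z in
Da/e, CCS in nm², coordinates in Å, drift times in ms; concentrations
are converted to nM internally before any model evaluation, since
protein and ligand are conventionally quoted in µM but K_D in nM.

## Charge-state envelopes and quantification

Positive-mode native electrospray charges by protonation only, so a
species of neutral mass M appears at m/z = (M + z·1.00728)/z. Spectra
are modelled as sums of Gaussians plus one constant baseline per
fitted window (real native spectra have slowly varying chemical
baselines; a constant is the simplest defensible form). Fits are
seeded from picked local maxima with sigmas from local FWHM estimates;
on non-convergence the optimiser restarts up to five times with
deterministically jittered sigmas, and a failed fit is returned
flagged, never silently.

Charge assignment minimises |observed − predicted m/z| over candidate
(species, charge) hypotheses within a tolerance, with a deterministic
tie-break (smaller residual, then lower charge, then candidate order).
Because a homodimer's mass is exactly twice its monomer's, dimer peaks
at even charges coincide exactly with monomer peaks at half the
charge; assignment therefore accepts optional per-species charge
ranges, mirroring how practitioners constrain assignments using the
observed envelope. Abundance tables sum areas over all assigned charge
states of a species — a choice the package fixes explicitly since
summing versus single-charge-state quantification is often left
unstated — and fractions are normalised over a caller-chosen label set
so that monomer:dimer ratios exclude DNA-bound species, which are
compared separately as occupancy.

Neutral masses are deconvoluted as the mean of z·(m/z) − z·m_H over
assigned charge states; ladders spaced by +79.966 Da (HPO₃) index
phospho-proteoforms relative to the lightest mass.

## TW-IMS calibration

Corrected drift time removes the m/z-dependent post-mobility flight
time, t′ = t_d − c·√(m/z). The EDC delay coefficient c is
instrument-specific and must be supplied; the module documents a
placeholder default (1.41 ms·(Da/e)^(-1/2)) used on both sides of all
synthetic round trips. The calibration fits ln(CCS_ref·√μ/q) against
ln t′ by ordinary least squares and applies
CCS = (q/√μ)·t′^m·exp(C). The reduced mass uses the helium mass
(4.0026 Da) by default because the protein calibrant reference values
are helium-scale CCS, even when the drift gas is nitrogen; the gas
mass is configurable and is stored with the calibration.

Arrival-time distributions are mapped to CCS sample-by-sample with no
Jacobian reweighting, matching common TW-IMS practice (the power-law
exponent is near one over a peak's width, so the correction is small
compared with instrumental peak-shape effects). The CCSD is the full
width at half the *global* maximum, between the outermost crossings
with linear interpolation — the convention that keeps a single number
meaningful for asymmetric, partially resolved conformer ensembles.
Conformer decomposition is a least-squares Gaussian-mixture fit with
quantile-based initialisation and jittered restarts; weights are
fractional areas sorted by mean.

## Titration model

The bound/unbound peak-area ratio of a 1:1 equilibrium is the closed
form given in the README; it is evaluated with a `hypot` formulation
of the discriminant to avoid overflow at very small K_D. The
denominator I(P) is the unbound *dimer* area only — monomer signal
never enters the ratio. K_D is optimised in log space (positivity
without bounds) from a default start at the geometric mean of [P]₀ and
the smallest nonzero [L]₀. Both the asymptotic standard error from the
Jacobian and an optional seeded bootstrap over titration points (200
resamples) are reported, because published ± values on titration K_D
measurements rarely state their provenance; the package asserts
neither interpretation. The default synthetic design is 3 µM protein
titrated with 0.2–6 µM ligand in 8 log-spaced points, the design used
for the study this package emulates.

## CIU analysis

Fingerprint columns are max-normalised by default (the standard CIU
contour convention; raw and sum-normalised forms are retained, and the
normalisation applied is recorded on the object). The transition
statistic is a logistic-step fit of the intensity-weighted column
centroid trace: c(CV) = c₀ + Σ aᵢ·σ((CV − vᵢ)/wᵢ), with aᵢ ≥ 0. This
centroid-trace method was chosen over feature-basis CIU50 fitting
because it is fully specified by the data containers here and recovers
printed transition voltages exactly on synthetic fingerprints; it is
the package's method of record. Step count is fixed by the caller or
chosen by BIC over 1–4 steps with a floored residual sum (the floor
keeps BIC finite on noiseless data, where extra components fit
degenerate zero-residual solutions). Starts come from peaks of the
trace derivative. Recovered voltages are quoted to ± one CV grid step;
synthetic tests use 1-V steps.

Compaction — the small CCS *decrease* some DNA-bound complexes show
under gentle activation before unfolding — is measured as the drop
from the initial centroid to the pre-transition minimum (voltages
below CV50₁ − 2w₁) and called present when it exceeds twice the local
detrended-centroid noise; the 2× threshold is a package choice for an
effect the literature only calls "marginal". Stability differences
between complexes are first-transition CV50 differences.

## Hard-sphere CCS

PA estimates the orientation-averaged projected area of the union of
atom spheres inflated by the buffer-gas radius: uniform random
rotations (normalised Gaussian quaternions), rejection sampling in the
projected bounding box, standard error from the orientation spread.
EHSS traces probe rays through specular reflections off the inflated
spheres (vectorised over rays, up to 100 reflections, rays exceeding
the cap discarded and counted) and averages box-area × (1 − cos θ) of
the total deflection; for convex bodies this equals PA analytically,
and concavity can only increase it — both facts are exercised as
tests. Defaults: helium-probe radius 1.0 Å, Bondi van der Waals
element radii (C 1.70, N 1.55, O 1.52, H 1.20 …, fallback 1.70 Å),
5×10⁴ trajectories over 50 orientations for EHSS and 64 orientations ×
4000 samples for PA — budgets that resolve a 50-atom body to well
under 1% Monte-Carlo error in about a second on one CPU. The
trajectory method (gas-molecule potentials) is intentionally not
implemented. Superposition RMSD uses the Kabsch algorithm; the
optional "percent" mode divides by the reference radius of gyration
and is explicitly a package convention, since percent-RMSD has no
standard normalisation.

## Synthetic data: what it does and does not show

The generators reproduce the *structure* of native IM-MS data —
Gaussian charge-state envelopes (monomer 11+–13+, dimer 16+–19+,
DNA-bound 18+–20+ scenarios), ±79.966 Da proteoform ladders, Gaussian
conformer families, logistic CIU transitions with optional ramped
compaction, exact binding-model titrations — with additive Gaussian
intensity noise floored at zero. They deliberately omit isotope fine
structure, salt adduction, detector saturation, ion statistics,
non-Gaussian peak shapes and real TWIMS field physics. Passing tests
therefore demonstrate that the *estimators are correct for their model
classes* (round trips are exact at zero noise, robust at realistic
noise), not that the models capture every instrumental artefact. The
construct masses are free parameters of the generators (default 37 kDa
subunit / 74 kDa dimer, a realistic size for the protein family
studied); ground truth is always the parameter, never a literature
mass. The DNA ligand duplex mass is likewise configuration: the κB
oligomer sequence is accepted as either the 20-mer or 21-mer printed
variant, neither hard-coded.

## Problem sizes and determinism

Synthetic spectra use a 0.25 Da/e grid over 2600–5000 m/z (~9600
points, 7 envelope peaks); CIU fingerprints a 1-V × 0.1 nm² grid
(61 × 400); titrations 8 points; Monte-Carlo CCS budgets as above.
These sizes make every stage's tests exact-to-tolerance while the full
suite runs in well under a minute. Every stochastic routine takes an
explicit integer seed; noiseless generation is bit-reproducible and
identical config + seed reproduce byte-identical CLI artifacts.

## Known limitations

* Charge assignment needs per-species charge ranges (or distinct
  masses) to separate a homodimer's even charges from its monomer.
* The asymptotic K_D standard error understates uncertainty when the
  titration reaches saturation (near-exact high-ratio points dominate
  the least squares); the bootstrap is the more honest interval there.
* BIC step-count selection assumes the fingerprint spans all
  transitions; traces without terminal plateaus are flagged by warning
  but midpoints near the edges are extrapolations.
* The EHSS engine is hard-sphere only: no long-range potential, so
  absolute values for small ions in nitrogen are not comparable with
  trajectory-method results.
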