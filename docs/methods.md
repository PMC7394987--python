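# Methods

## Acquisition model

The pipeline targets a dual-time-resolution DCE protocol at 3 T: two
alternating saturation-prepulse sequences, a *fast* one (dynamic scan
interval 3.2 s, 29 volumes) that samples the bolus first pass, and a
*slow* one (interval 30.5 s, 30 volumes) that follows the leakage phase,
with TR/TE/TD = 5.3/2.5/120 ms. Both sequences acquire volumes before
contrast injection; the bolus is injected during the fast sequence.

The signal model is pure saturation recovery,
`S = S₀ (1 − exp(−TD·R1))` with `R1 = R10 + r1·C`. The readout's
perturbation of the recovery is neglected — standard for short-TD
prepared acquisitions — which makes the conversion invertible in closed
form. The readout flip angle is therefore carried only as metadata.
Relaxivity defaults to `r1 = 5.0 L·mmol⁻¹·s⁻¹` (gadobutrol at 3 T,
literature-typical) and is configurable.

Noise pushes some voxel-time points above the saturation ceiling, where
the log in the inversion would be undefined; those points are clamped at
a configurable fraction of the ceiling (default 0.999) and flagged,
never silently made non-finite.

## Vascular input function

The VIF is the mean signal of ≥ 20 sagittal-sinus voxels, expressed as
an enhancement ratio over the pre-contrast mean, mapped to whole-blood
concentration through a strictly monotone calibration table (monotone
piecewise-cubic/PCHIP inversion), and divided by `1 − Hct` to give
plasma concentration. The hematocrit is a single global constant
(default 0.45) applied symmetrically in simulation and analysis, so it
cancels in round-trip tests. Because the Patlak design refuses to
extrapolate beyond the VIF's time coverage while the fast sequence ends
early in the session, the sinus curve is read from both sequences (each
with its own baseline) and merged.

The synthetic calibration table is generated from the same
saturation-recovery law at the blood T10 (1650 ms), tabulated at
2.5 × 10⁻³ mM steps from −1 to 40 mM. The dense tabulation makes the
PCHIP inversion exact to ≈ 10⁻¹⁰ mM; the small negative branch lets
noisy pre-bolus ratios below one map to retained negative
concentrations, which the histogram noise correction downstream
requires.

## Patlak estimation

`(Ki, vp)` solve the ordinary-least-squares problem
`Ct = Ki·∫Cp + vp·Cp` over the usable (post-bolus) time points of the
merged series, with the running integral by the trapezoid rule in
mM·min so `Ki` is in min⁻¹ regardless of the input time unit. Bolus
arrival is detected as the first sample where `Cp` exceeds 5 % of its
peak (configurable). Fast and slow phases are fitted jointly. All
voxels share one design matrix, so a whole map is a single vectorized
solve. Rank-deficient designs and voxels with non-finite concentrations
are flagged with NaN sentinels, counted, and excluded downstream.
Negative `Ki` is retained by contract. No spatial regularization is
applied; voxels are independent.

## Histogram noise correction

Per-voxel `Ki` noise at these leakage rates is symmetric about zero, so
each ROI histogram is built on uniform bins symmetric about zero (bin
width defaulting to Freedman–Diaconis on the pooled |Ki|), and every
positive bin is corrected by `max(0, raw(b) − raw(mirror(b)))`; all
non-positive bins are zeroed. The noise-corrected mean divides the
corrected mass by the **full ROI voxel count** (default), so
non-leaking voxels contribute zero; a corrected-mass ("leaking")
denominator is available and the convention is recorded in the output.

A property worth knowing: the per-bin clamp at zero makes the corrected
mean of a *pure-noise* ROI strictly positive in expectation, decaying
roughly like N⁻¹ᐟ³ with ROI size. The package's calibration tests
measure this: the corrected mean under the null shrinks monotonically
over 10²–10⁴ voxel ROIs but remains statistically distinguishable from
zero (the seed-to-seed spread shares the bias's scaling, so widening
bins does not remove it). Mixture recovery is unaffected in practice:
for ROIs where a fraction f of voxels leak at rate k (f ∈ {0.1, 0.5},
k = 2 × 10⁻⁶ min⁻¹, noise SD 10⁻⁶ min⁻¹, 10⁴ voxels), the corrected
mean recovers f·k to well within 10 % over 50 replicates, because the
mirror subtraction is exactly unbiased apart from the clamp term.

## Synthetic phantom

The phantom is a small 3D grid (default 32 × 32 × 16) of box-shaped
regions: white matter, gray matter, disjoint primary / secondary /
tertiary cortical sub-regions (each ≥ 500 voxels, enough for stable
histograms), and a sinus box (≥ 20 voxels). Default kinetics sit at the
levels reported for healthy middle-aged to older adults: per-region Ki
medians of 11.4 / 9.5 / 4.4 / 3.4 / 9.2 × 10⁻⁷ min⁻¹ (white matter,
gray matter, primary, secondary, tertiary), vp of 0.8–1.5 %, T10 of
1100 ms (WM), 1800 ms (GM) and 1650 ms (blood).

The input function is a parametric stand-in for a measured sinus curve:
a gamma-variate rise reaching a configurable peak (default 6 mM whole
blood ≈ 10.9 mM plasma) 8 s after bolus arrival, then a biexponential
washout (rates 1/30 and 1.7 × 10⁻³ s⁻¹, fast fraction 0.7). The
injected dose fixes the total agent, not the peak plasma concentration,
so the peak is exposed as a free parameter. Bolus arrival is placed
after the fast sequence's pre-contrast volumes, and the peak falls
inside the fast window.

The phantom's *true* plasma curve is defined as the piecewise-linear
interpolant of the parametric curve on the merged acquisition grid.
This is a deliberate design choice: trapezoid integration in the fitter
is then exact, so the noiseless phantom is a genuine fixed point of the
whole pipeline (voxel-wise Ki error < 10⁻⁹ min⁻¹ end to end, measured
≈ 10⁻¹³), and any regression in any stage surfaces as a recovery error
rather than being hidden inside quadrature error.

Noise is Rician by default (magnitude MRI), with a Gaussian option for
analytic tests, at a standard deviation of `noise_sigma_rel` times each
voxel's baseline signal. The default `noise_sigma_rel = 2 × 10⁻⁵` was
calibrated so that per-voxel Ki noise is ≈ 1.3 × 10⁻⁷ min⁻¹ — about
11 % of the white-matter rate — which keeps the generator's
parameter-recovery contract (mean Ki error below 5 % of the true rate
over 200 replicate voxels) satisfiable with margin. This is far milder
than in-vivo thermal noise, under which per-voxel Ki estimates are
dominated by noise (the reason the histogram correction exists);
passing recovery tests on this phantom therefore demonstrates pipeline
correctness, not in-vivo precision. The phantom also omits anatomy,
partial-volume effects, B1/flip-angle inhomogeneity, motion and
k-space artifacts, and assumes perfect co-registration.

## Synthetic cohort

Cohorts default to the reference study's conditions: n = 57, ages from
a truncated normal (mean 65.8, SD 10.2, range 47–91), 52.6 % male,
systolic blood pressure 141.3 ± 17.2 mmHg with a mild age slope, BMI
27.7 ± 4.5, diabetes prevalence 17.5 %, smoking 14 %. WMH volume is
log-normal with a strong standardized age effect (0.55); cortical
thickness (2.45 ± 0.10 mm) and hippocampal volume (6.5 ± 0.7 cm³)
decline with age (standardized −0.5 and −0.3). These integrity-measure
parameters are the package's own realistic choices where no values are
reported.

Per-ROI mean Ki is generated on the cube-root scale, where the analysis
model is linear: `y = c + s·(β·z_age + β_sex·z_sex + √(1−β²−β_sex²)·ε)`
with `c` the cube root of the programmed median and `s` matched to the
programmed interquartile range (the reported Table values are the
defaults; programmed age effects 0.306 / 0.286 / 0.145 / 0.098 /
0.307). Back-transforming `y³` yields the right-skewed Ki
distribution, and re-fitting after the cube-root transform recovers the
programmed standardized β (default sex effect 0). A full-mediation mode
routes the age path entirely through one integrity measure, with the
loading chosen so the marginal age effect is unchanged.

A consequence worth stating plainly: with a true standardized age
effect of 0.306 at n = 57, the exact noncentral-t power of the
two-sided 5 % test is 0.64, and the simulated detection rate matches
(≈ 0.63–0.66). A single cohort of that size detecting the effect (as
the reference cohort did at p = .024) is compatible with, but more
fortunate than, the average draw.

## Statistics

Ki means are cube-root transformed with the signed convention
(`sign(x)·|x|^⅓`), required for real-valued output at negative
corrected means; WMH volumes are log-transformed (configurable offset
for zeros). Standardized coefficients are `b·SD(x)/SD(y)` with sample
SDs, binary predictors standardized identically; p-values are
two-sided t-tests at α = .05; no multiple-testing correction across the
five ROIs is applied by default. Interaction models mean-center age and
the integrity measure before multiplying, prune the interaction when
p ≥ .05, and report main effects from the reduced model (both stages
are returned). Missing data are handled complete-case per model with
dropped-row counts logged; constant predictors are rejected by name.

## Problem sizes used in validation

The test and acceptance workloads use the default 32 × 32 × 16 phantom
(≈ 8 000 brain voxels), 10⁴-voxel synthetic ROIs with 50 replicates for
the histogram calibrations, 20 cohorts of n = 500 for effect-size
recovery, 200 cohorts of n = 57 for detection-rate estimates, and
500–1000 null cohorts for type-I calibration — sizes chosen so every
Monte-Carlo standard error is small relative to the tolerance it is
compared against.

## Known limitations

- The Patlak model ignores reflux and exchange; extended Tofts or
  two-compartment models are out of scope.
- The in-vitro calibration curve's exact shape for real data is
  scanner-specific; it is pluggable, and only the synthetic default is
  validated here.
- The clamp in the histogram correction biases the null corrected mean
  slightly positive (see above); comparisons between ROIs or subjects
  with very different voxel counts should keep the N⁻¹ᐟ³ dependence in
  mind.
- Motion correction, registration, T1-map estimation and segmentation
  are upstream of this package; inputs are assumed co-registered.
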