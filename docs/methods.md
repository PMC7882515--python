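# Methods

This note documents the models, defaults and design choices behind
`dkiasl`, and what the synthetic data do and do not establish about real
acquisitions.

## Diffusion kurtosis model and fit

The voxel signal model is

    ln[S(n,b)/S0] = −b D(n) + (1/6) b² MD² W(n),
    D(n) = Σᵢⱼ nᵢnⱼ Dᵢⱼ,   W(n) = Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ,

with *D* symmetric (6 unique components, mm²/s) and *W* fully symmetric
under index permutation (15 unique components, dimensionless). The
directional apparent kurtosis is K(n) = (MD/D(n))² W(n).

**Fitting.** The model is linear in (ln S0, D, V) with V = MD²·W, giving a
22-parameter linear system against ln S. We solve it in two stages:
ordinary least squares, then weighted least squares with weights equal to
the squared predicted signals from the first pass — the first-order
variance-stabilizing weighting for log-transformed magnitude data. W is
recovered as V/MD². The fit refuses schemes with fewer than two non-zero
shells or fewer than 15 distinct encoding directions (the system would be
rank-deficient). Voxels with non-positive or non-finite signals are flagged
unfittable rather than raising, so volume sweeps never abort.

**Constraints and derived metrics.** Diffusion eigenvalues are floored at
eps_D = 1e-6 mm²/s; per-direction K(n) is clamped to [K_min, K_max] =
[0, 3] before MK averaging (standard noise-robustness practice; both
exposed in `FitOptions`). MK defaults to the average over the scheme's 15
distinct encoding directions, mirroring a 15-direction vendor computation;
a dense 256-point spherical (Fibonacci) set is available via
`mk_directions="sphere"`. FA of the all-zero tensor is defined as 0
(continuity; avoids 0/0). Units throughout: b in s/mm², D/MD in mm²/s,
W/MK/FA dimensionless.

**Encoding directions.** The shipped 15-direction set is a deterministic
Fibonacci hemisphere lattice. Vendor direction tables vary and the specific
vendor estimator behind clinical DKI maps is not public, so numerical
equality with any scanner's maps is not claimed — only equality with this
package's own forward model, which the round-trip tests establish to
~1e-12 relative error.

## ASL quantification

Single-delay pcASL with the closed-form kinetic scaling

    CBF = λ (1 − e^(−t_sat/T1g)) · ΔS · e^(ω/T1b)
          / [2 α T1b (1 − e^(−τ/T1b)) · S0]

computed internally in mL/g/s and reported ×6000 as mL/100 g/min. Only the
post-labeling delay has a protocol-documented value (ω = 1.5 s); the other
constants default to consensus 3 T values — λ = 0.9 mL/g, α = 0.85,
T1b = 1.65 s, T1g = 1.2 s, t_sat = 2.0 s, τ = 1.5 s — and are overridable
per run. The labeling-duration factor is implemented as (1 − e^(−τ/T1b));
a positive exponent would make the denominator negative and the flow
unphysical. Background suppression, motion correction, filtering and
partial-volume correction are out of scope: phantoms are generated
artifact-free, and real inputs are assumed preprocessed. Voxels with
non-positive reference signal are set to NaN, never zero.

## ROI protocol

The default atlas enumerates the protocol's 12 bilateral regions
(hippocampal head/body/tail, posterior cingulate, precuneus, three
dorsal-thalamus subnuclei, lenticular nucleus, caudate head, frontal and
occipital white matter) in both hemispheres. Mirroring flips voxel i to
N−1−i along the left–right axis, assuming the midsagittal plane at the
grid midpoint (manual placement on visually aligned images cannot be
reproduced; user-supplied label maps are accepted). The in-plane area gate
is 18–22 mm² per slice. Replicates are averaged within rater, then across
raters; with a balanced design this equals the grand mean. Reliability uses
ICC(3,1) — two-way mixed, single measure, consistency — because the two
raters are fixed; absolute-agreement ICC(2,1) is available. The 0.75 gate
follows the conventional "good reliability" threshold. Whether reliability
is assessed per region-metric over subjects (library default,
`icc_report`) or pooled over regions (single-subject CLI mode) is
documented at each call site.

## Cohort inference

- Sex counts: Pearson chi-squared without continuity correction.
- Region families: one family = 12 regions × one metric × one hemisphere.
  Per region, Shapiro–Wilk per group at α = 0.05 gates between one-way
  ANOVA and Kruskal–Wallis (tie-corrected); groups with n < 3 route to the
  rank test with a warning. BH-FDR is applied across the family to the
  omnibus p-values and, separately, to each pairwise contrast (both
  reported; the family definition is the closest literal reading of
  "per hemisphere, per metric" and is configurable).
- Post-hoc: Tukey–Kramer HSD on the ANOVA branch; Dunn's rank test with
  BH adjustment over the three pairs on the rank branch. Degenerate
  all-equal data yields p = 1 by convention.
- Partial correlation: x and y residualized on an intercept + covariates
  by least squares; Pearson r of residuals tested with df = n − 2 − k.
  Sex is encoded M = 0, F = 1.
- ROC: AUC by the Mann–Whitney statistic with midrank ties; the positive
  class is always named explicitly and never auto-flipped; 95% CI by
  DeLong's placement-value variance. Combined scores come from an
  unpenalized maximum-likelihood logistic regression on standardized
  features; on separation or non-convergence the fit falls back to a ridge
  penalty of 1e-4 and the result is flagged.

## Synthetic data

**Phantom.** A block phantom on a 48 × 48 × 12 grid at 0.9375 × 0.9375 ×
4 mm (240 mm field of view over a 256 matrix, scaled to a 48-voxel desk
grid; protocol slice thickness). Each of the 24 regions is a 4 × 6 × 2
block — 24 voxels per slice, 21.1 mm², inside the area gate — mirrored
exactly across the midline; the brain mask is the union of the blocks
(1,152 voxels), which keeps voxelwise fitting fast while exercising every
stage. Region signals come from the forward kurtosis model; the kurtosis
tensor is built as K·sym(D⊗D)/MD², which makes K(n) constant at the
region's MK and hence exactly recoverable (an anisotropically oriented
option exercises rotation invariance instead). ASL difference signals come
from the exact algebraic inverse of the CBF equation. Rician noise
(magnitude of a complex Gaussian) is optional with SNR defined at the b0
signal. The phantom is piecewise constant and artifact-free: passing tests
demonstrate internal consistency of model, fit and extraction, not
robustness to motion, distortion, partial volume or physiological noise.

**Cohort.** Three groups of 33/27/31 subjects (EC / SCD plus / aMCI).
Region-metric values are Gaussian around region baselines (typical
gray/white-matter MK/FA/MD/CBF values) with within-group SDs of 0.06 (MK),
0.04 (FA), 0.06e-3 mm²/s (MD), 6 mL/100 g/min (CBF), and an equicorrelated
between-region structure (ρ = 0.3) within each subject-metric. Group
effects are configured in SD units; the shipped pattern follows the
studied disease topography: SCD plus shows MK/CBF deficits concentrated in
the hippocampal head and posterior cingulate with an elevated left
precuneus, aMCI shows broader and deeper deficits, MD changes appear only
in aMCI. Effect magnitudes were calibrated a priori so the primary
left-hippocampal-head MK deficit is ≈1 SD (single-region binormal AUC
≈ 0.76) and the combined multi-region AUCs fall in the 0.75–0.90
discrimination regime typical of such studies; a log-normal option
exercises the rank-test branch. Covariates (age, sex, education) are drawn
per group from matched distributions, so they are non-confounding by
construction. Scores (AVLT immediate/delayed/recognition, MMSE, MoCA) are
linear in the standardized within-group deviations of selected region
metrics plus Gaussian noise; the delayed-recall score couples to left
hippocampal-head MK (weight 0.45), left PCC MK (0.25) and left
hippocampal-head CBF (0.30), giving a within-group partial correlation of
≈0.5 with left Hip-head MK. Everything is deterministic under the config
seed.

## Numerical choices

- Round trips (fit∘predict, quantify∘predict) hold to ~1e-12 relative;
  tests assert 1e-6/1e-9.
- The diffusion tensor is re-symmetrized after eigenvalue flooring to
  remove eigen-reconstruction round-off.
- ICC sums of squares use interaction residuals directly rather than
  subtraction, so exactly-agreeing raters give ICC = 1.0 exactly.
- BH adjusted p-values are the step-up min-form, capped at 1; rejections
  equal {adjusted p ≤ q} identically.
- Degenerate inputs: all-equal groups give post-hoc p = 1; zero
  between-target variance makes ICC undefined (error); empty direction
  sets, single-class labels and collinear covariates raise.

## Known limitations

- Voxelwise MK at SNR 50 on the 31-volume scheme has an intrinsic
  estimator SD of ≈0.08 (the optimally weighted linear estimator's
  error-propagation bound gives ≈0.078 for a typical gray-matter voxel);
  per-voxel median |MK error| is therefore ≈0.055–0.06 at that SNR, and
  region averaging — as in the ROI protocol — is what delivers precise MK
  estimates. Simulation sizes in tests and the acceptance script (100
  round-trip draws, 500 noise voxels, 200–500 cohort replicates) were
  chosen to keep the full suite in the minutes range on one CPU.
- No eddy/motion/distortion correction, registration, or anatomical
  segmentation: inputs are assumed preprocessed and ROIs user-supplied or
  synthetic.
- Axial/radial kurtosis, tractography, multi-compartment diffusion models,
  transit-time ASL modeling and multi-delay ASL are out of scope.
- The vendor estimator, constraint scheme and MK direction set behind
  clinical DKI maps are unpublished; numerical equality with scanner
  output cannot be claimed.
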