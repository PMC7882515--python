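# dkiasl

Diffusion-kurtosis and arterial-spin-labeling ROI analysis for three-group
neuroimaging studies of early cognitive decline.

The package implements, as a tested and reusable pipeline, the quantitative
workflow of studies that compare elderly controls (EC), subjective cognitive
decline "plus" (SCD plus) and amnestic mild cognitive impairment (aMCI)
using mean kurtosis (MK), fractional anisotropy (FA), mean diffusivity (MD)
and cerebral blood flow (CBF) measured in 24 mirror-symmetric regions of
interest. It is aimed at neuroimaging methodologists who want every stage of
such an analysis — signal model, quantification, ROI protocol, reliability
gate, and group inference — to be explicit, scriptable and testable without
patient data: a synthetic-data module generates phantoms and cohorts with
the statistical structure the analysis assumes.

## The models

**Diffusion kurtosis.** For encoding direction *n* and weighting *b* the
signal follows

    ln[S(n,b)/S0] = −b Σᵢⱼ nᵢnⱼ Dᵢⱼ + (1/6) b² MD² Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ

with diffusion tensor *D* (mm²/s), dimensionless kurtosis tensor *W*, and
MD = tr(D)/3. The directional apparent kurtosis is
K(n) = (MD/D(n))² W(n); MK averages K(n) over the encoding directions,
FA is the eigenvalue-dispersion index of *D*. Fitting is a two-stage
linearized weighted least squares in the 22 parameters
(ln S0, D, V = MD²·W); the default acquisition is 1 b0 + 15 directions at
b ∈ {1000, 2000} s/mm² (31 volumes).

**pcASL CBF.** The control−label difference ΔS converts to flow by

    CBF = λ (1 − e^(−t_sat/T1g)) · ΔS · e^(ω/T1b) / [2 α T1b (1 − e^(−τ/T1b)) · S0]

scaled ×6000 to mL/100 g/min; defaults are consensus 3 T constants with
post-labeling delay ω = 1.5 s. The model is linear in ΔS/S0 and inverts
exactly (used by the phantom generator).

**ROI protocol and inference.** Bilateral ROIs are mirror-symmetric
(left-to-right flip across the grid midline) with an 18–22 mm² in-plane
area gate; measurements are averaged over three replicates within each of
two raters, whose agreement is gated by ICC(3,1) > 0.75. Group inference
runs, per (metric, hemisphere) family of 12 regions: a Shapiro–Wilk
normality gate → one-way ANOVA or Kruskal–Wallis → Tukey–Kramer or Dunn
post-hoc, with Benjamini–Hochberg FDR over the family; covariate-adjusted
Pearson correlations (age, sex, education) link region metrics to
neuropsychological scores, and single and logistic-combined ROC/AUC (DeLong
95% CI) quantify group discrimination.

## Worked example

`examples/01_voxel_forward_and_fit.py` forward-simulates one voxel and fits
it back:

```
scheme: 31 volumes, shells (1000.0, 2000.0)
signal at b=0: 100.0, strongest attenuation: 21.52
MD  truth 9.000e-04  fitted 9.000e-04 mm^2/s
FA  truth 0.200000   fitted 0.200000
MK  truth 0.800000   fitted 0.800000
```

`examples/05_cohort_group_statistics.py` generates the default 91-subject
cohort and runs the inference stage; with seed 42 it prints, among others:

```
AVLT-DR ~ left Hip (h) MK within SCD plus, adjusted for age/sex/education:
r = 0.477, p = 0.0183
combined MK ROC (SCD plus vs EC over 6 regions): AUC = 0.819 (95% CI 0.711-0.927)
```

meaning: the simulated memory score co-varies positively with left
hippocampal-head MK inside the SCD-plus group after removing covariate
effects, and pooling six regional MK values through logistic regression
discriminates SCD plus from controls well above chance. The other examples
cover CBF quantification, the phantom→maps→ROI round trip, and the
two-rater ICC gate.

## Command line

The same stages are available as a thin CLI:

```bash
dkiasl simulate --out data/                               # synthetic dataset
dkiasl fit --dwi data/dwi.nii.gz --bval data/dwi.bval --bvec data/dwi.bvec \
           --asl-control data/asl_control.nii.gz --asl-label data/asl_label.nii.gz \
           --m0 data/m0.nii.gz --out maps/
dkiasl roi --maps maps/ --atlas data/atlas.nii.gz --out roi/
dkiasl stats --cohort data/cohort.csv --out stats/
```

Exit codes: 0 ok, 2 configuration error, 3 data error. Every stage writes a
JSON report embedding the package version, config hash, and seeds.

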