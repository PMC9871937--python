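# Methods

## Scientific setting

Leber's hereditary optic neuropathy (LHON) is a mitochondrial disease in
which neurons' energy supply is compromised. One way to ask whether the
brain's *neurovascular coupling* — the match between neuronal activity
and microcirculatory blood supply — is disturbed is to compare a
resting-state measure of intrinsic neuronal activity against a perfusion
measure, voxel by voxel. This package implements that analysis:

- **ReHo** (regional homogeneity): Kendall's coefficient of concordance
  (W) between each voxel's BOLD time series and its 26 neighbours, a
  rank-based measure of local synchrony used as a proxy for regional
  spontaneous neuronal activity.
- **Relative CBF**: an arterial-spin-labeling perfusion map divided by
  its in-brain global mean.
- **Coupling index**: the voxel-wise ratio ReHo/CBF of the two globally
  scaled, smoothed maps. Elevated values read as more neuronal activity
  per unit perfusion.

Group inference compares three groups — acute patients (duration ≤ 1
year), chronic patients (> 1 year) and healthy controls — with age and
gender covariates, then relates the coupling index to disease duration
and neuro-ophthalmological metrics.

## Pipeline

Per subject, in order (all inputs assumed already in a common 2 mm
isotropic space; registration is out of scope):

1. **Discard** the first `n_discard` volumes (default 10) of BOLD and
   motion in lockstep.
2. **Nuisance regression** of each in-mask voxel on: intercept,
   normalised linear trend, WM and CSF mean signals (plain means over
   the supplied masks, no erosion), the Friston-24 motion set (6
   parameters, squares, one-frame lags, lagged squares; lag of the
   first frame is 0), and one indicator column per frame whose Power
   framewise displacement (head radius 50 mm) exceeds 0.5 mm. Spikes
   are regressed, not deleted, so series length is preserved for the
   concordance computation. All-zero and linearly dependent columns are
   pruned greedily left-to-right, which keeps the design full rank and
   deterministic; a spiked frame's residual is exactly zero whenever an
   indicator (or a combination spanning it) survives pruning.
3. **Band-pass** 0.01–0.10 Hz with an ideal rectangular FFT filter:
   coefficients with frequency in the closed interval are kept, all
   others (including DC) zeroed; no padding. Filtering twice equals
   filtering once.
4. **ReHo**: W over each voxel's 3×3×3 neighbourhood using midranks
   (no tie-correction term, per the original formulation; band-passed
   data are effectively tie-free). Mask-edge voxels use the K < 27
   available in-mask neighbours and are flagged in a QC mask rather
   than dropped; neighbourhoods containing a constant series are set to
   0 and flagged. The map is then scaled by its in-brain mean and
   smoothed.
5. **CBF**: mask, clip negative ASL values to zero (counted), scale by
   the in-brain mean, smooth. Scaling after masking and before
   smoothing; smoothing is mask-renormalised (numerator/denominator
   convention), so a constant map is unchanged and zeros outside the
   mask do not bleed in. The in-mask mean is exactly 1 before smoothing
   and within ~5e-3 of 1 after it — renormalised smoothing preserves
   constants, not means.
6. **Coupling**: ReHo/CBF where CBF ≥ ε (default ε = 0.05 of the
   global-mean-normalised CBF). The guard exists because mask-edge
   smoothing can produce near-zero denominators; excluded voxels are
   counted, never infinite. Because both inputs are globally scaled,
   the ratio is invariant to positive rescaling of either raw input.

Smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in voxel units, default
6 mm isotropic FWHM on 2 mm voxels.

## Group inference

The voxel-wise model is cell-means coded: one column per group plus
mean-centred age and 0/1 gender (male = 1). The omnibus statistic is
the nested-model F of the three-mean model against the single-mean
model, df (2, N−5).

**Cluster-extent FWE** is controlled by permutation rather than
random-field theory: the F map is thresholded at the parametric
cluster-forming p (default 1e-3), components are labelled with
26-connectivity (configurable: 6/18/26 — SPM's default is 18), and the
null distribution of the maximum cluster size is built by
Freedman–Lane permutation: residuals of the covariates-only model are
permuted across subjects so age and gender are respected under the
null. A cluster's corrected p is the proportion of permutations whose
maximum cluster size reaches its size. Permutation was chosen over
random-field theory because it is exact under exchangeability and
directly testable by simulation; the trade-off is a Monte-Carlo floor
of 1/n_perm on corrected p-values.

**Post-hoc contrasts** are computed inside the covariate-adjusted
model (not raw two-sample tests): each pairwise group difference is a
linear contrast of the cell means with the pooled residual variance,
t with N−5 df, flagged at the family threshold
0.05/(nROIs·nMeasures·nPairs) — 0.05/27 = 1.85e-3 for 3 ROIs × 3
measures × 3 pairs. ROIs come from the significant clusters when any
exist, otherwise from the ground-truth planted regions (recorded in
the run manifest).

**Scalar tests** mirror what a cohort table supports: one-way ANOVA
and pooled-variance t recomputed exactly from (n, mean, SD) summaries;
Pearson χ² without continuity correction; an exact conditional (Fisher)
r×c test by full enumeration of tables with the observed margins
(intended for small demographic tables; the enumeration budget guards
against misuse); Pearson correlation with t-based two-sided p.

## Clinical regression

Coupling–clinical association is modelled in two stages: residualise
the ROI coupling mean on [1, age, gender] (constant covariate columns,
e.g. an all-male patient subset, are dropped), then fit on patients
only (duration is undefined for controls):

- linear OLS, and
- the three-parameter exponential Y = a·e^(bx) + c by nonlinear least
  squares with multi-start initialisation: a log-linear pre-fit on the
  detrended |y − median| supplies one rate candidate, augmented by a
  sign-symmetric grid (±0.2, ±0.05, ±0.01, plus the same rescaled to
  the predictor range); for each candidate b the amplitude and offset
  are profiled linearly, then the full model is refined; the best SSE
  wins. Non-convergence from every start yields a flagged fit, never a
  silent failure.

Adjusted R² is 1 − (1−R²)(n−1)/(n−p−1) with p = 1 (linear) and p = 3
(exponential); it may legitimately be negative. The exponential's
p-value is the extra-sum-of-squares F of the 3-parameter model against
intercept-only (df 2, n−3), a definition chosen because the fit is
nonlinear and no closed-form slope test exists. The regression family
threshold is 0.05/(3 ROIs · 5 measures · 2 models) = 1.67e-3.

The two-stage residualise-then-fit scheme slightly biases coefficients
relative to a joint covariate-inclusive nonlinear model; it was chosen
for interpretability and because the covariates here are nuisance, not
of interest.

## Synthetic cohort

The generator produces the full study input — 4-D BOLD, motion traces,
CBF maps, brain/WM/CSF masks, region labels and a cohort table — with
known ground truth, so every downstream stage is testable without any
acquisition.

**BOLD.** Each voxel's series is λ·s + (1−λ)·n on a baseline of 100,
where s is a region-shared and n a voxel-independent signal, both
synthesised in the frequency domain with random phases restricted to
0.01–0.10 Hz and normalised to unit variance. Synthesis in the passband
is deliberate: the planted coherence survives the band-pass stage, so
ReHo behaviour is isolated from filter artifacts. λ ∈ [0, 1] controls
true regional homogeneity (λ = 1 → W → 1; λ = 0 → E[W] = 1/27). WM and
CSF voxels carry no coherent signal — only noise and a strong copy of
the slow drift — otherwise their mean regressors would remove
gray-matter signal rather than physiological nuisance. A slow drift
(linear + low-frequency sine) loads on all tissue with 5× weight in
WM/CSF, and motion-locked global intensity jumps coincide with
sustained 0.8 mm translation steps planted at Bernoulli(spike_rate)
frames, so FD > 0.5 mm exactly there and the spike regressors have
something real to remove.

**CBF.** A smooth positive baseline field (shared across subjects) ×
a region/group multiplicative factor × mild smooth multiplicative
subject noise (log-normal, 5%); zero outside the brain.

**Cohort table.** Ages uniform 10–55 y; gender binary with the
male-heavy imbalance characteristic of LHON cohorts (90%/62%/73% male
by group); durations ≤ 12 months (acute) / > 12 months (chronic,
exponential tail, capped at 422) / missing for controls; four clinical
metrics drawn from group-conditional normals matching the study
summaries; and a planted temporal-region coupling value following
Y = a·e^(b·duration) + c + noise with default (a, b, c) =
(0.08, 0.006, 1.05) and noise SD 0.08. The positive, gentle rate means
coupling grows from ~1.13 (acute) to ~2 at the longest durations —
qualitatively the saturating rise reported for sensorimotor coupling
versus duration, parameterised with b > 0 so "growth with duration"
corresponds to a positive rate constant.

**Planted group effects** (defaults) mirror the study's qualitative
findings: a "calcarine" (visual-analogue) region with CBF factor 0.8
in both patient groups and coherence unchanged — reduced perfusion
with preserved neuronal activity; a "temporal" region with CBF 0.75
and λ raised 0.40 → 0.55 in chronic patients only. Phantom geometry
matters more than is obvious: the planted regions must be a small
fraction of the brain (calcarine ≈ 7.6%, temporal ≈ 1.5% of in-mask
voxels) because a large planted ReHo elevation inflates that subject's
global ReHo mean and spuriously depresses their scaled ReHo everywhere
else — with regions sized like real clusters (1–2% of brain) the
contamination is negligible, as in real data. At the same time each
region spans several smoothing-kernel widths, so the 6 mm kernel does
not wash the effect out of ROI means.

**What the phantom does not model:** anatomy, MRI physics (labeling
efficiency, T1 relaxation), registration error, spatially varying
autocorrelation, physiological noise spectra, or within-group effect
heterogeneity (group effects are homogeneous; noise parameters are the
only within-group variation). Passing tests therefore demonstrate the
*statistical machinery* — not that real LHON data would yield these
effect sizes.

## Validation studies and problem sizes

All replicate studies live in `nvcoupling.experiments` and are run both
by the test suite and by `scripts/acceptance.py`.

- **FWE calibration**: 200 null cohorts (all CBF factors 1, equal
  coherence), 8 subjects/group on a 16×16×12 grid, 500 permutations
  each; the empirical family-wise error must fall in the 99% binomial
  interval around 0.05 ([0.010, 0.090] at 200 replicates). The null
  uses CBF-only maps because exchangeability is what is being tested,
  and prepared CBF maps carry the same smoothness structure the
  cluster test sees in a full run.
- **Effect-pattern recovery**: 20 cohorts at 15 subjects/group, 210
  timepoints (200 usable after discarding — the acquisition length the
  analysis is designed around), default grid; the post-hoc table over
  ground-truth ROIs must reproduce the planted direction/significance
  pattern in ≥ 90% of replicates.
- **Exponential recovery**: a 49-patient cohort (20 acute + 29
  chronic); recovered (a, b, c) must each lie within 3 standard errors
  of truth with a positive rate constant; noiseless data must be
  recovered to 1e-4 relative.

These sizes were chosen once as desk-scale study conditions (each study
minutes, not hours, on one CPU) and are not tuned per run.

## Numerical choices

- Ranks by double argsort (ordinal) with a midrank fallback when ties
  are detected — exact for continuous data, correct under ties.
- F statistics via orthonormal-basis projections (QR), identical to
  normal equations to ~1e-9 relative and fast enough to permute.
- The permutation p is the plain proportion of permutations with max
  cluster size ≥ observed (no +1 smoothing); with ≥ 500 permutations
  the difference from the smoothed convention is below the Monte-Carlo
  noise floor.
- Peak coordinates are reported in mm with the grid origin at voxel
  (0,0,0) and axes along the array dimensions (affine = diag(voxel
  size)); there is no anatomical template, so no scanner/MNI origin.
- Seeds: every stochastic component derives from explicit integer
  seeds via numpy SeedSequence spawning; identical spec + seed gives
  byte-identical images and tables.

## Known limitations

- Registration, slice timing and motion *correction* (resampling) are
  out of scope; real data must arrive realigned on the common grid.
- Cluster-extent inference assumes exchangeable subjects under the
  null; heavy-tailed or heteroscedastic group noise would need a
  different permutation scheme.
- The Fisher exact test enumerates exhaustively and is only for small
  tables (it refuses rather than approximate).
- The exponential model is only weakly identified when b·range(x) ≪ 1;
  the reported standard errors (curvature-based) honestly reflect this
  but the fit may then be interchangeable with the linear one.
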