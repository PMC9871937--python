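# nvcoupling

Voxel-wise neurovascular coupling analysis for multi-modal resting-state
MRI, built around the ReHo/CBF ratio, with a fully synthetic validation
cohort.

## What problem this solves

In Leber's hereditary optic neuropathy (LHON) — and other conditions
where neuronal energy supply is suspect — the question is whether
intrinsic neuronal activity and microcirculatory blood supply remain
matched. This package quantifies that match as the voxel-wise ratio of
two globally scaled maps:

- **ReHo** (regional homogeneity): Kendall's coefficient of concordance
  W of each voxel's BOLD time series with its 26 neighbours,

      W = 12 Σᵢ (Rᵢ − K(n+1)/2)² / (K²(n³ − n)),

  K ranked series over n timepoints, rank sums Rᵢ — a proxy for
  regional spontaneous neuronal activity;
- **relative CBF**: an arterial-spin-labeling perfusion map scaled by
  its in-brain global mean.

The **coupling index ReHo/CBF** is elevated where neuronal activity is
maintained on reduced perfusion. The package implements the full chain:
BOLD cleaning (volume discarding, nuisance regression with Friston-24
motion terms and FD > 0.5 mm spike indicators, 0.01–0.10 Hz ideal
band-pass), ReHo, CBF preparation, the ratio map, voxel-wise three-group
ANCOVA with permutation cluster-extent FWE correction, covariate-adjusted
post-hoc contrasts, Pearson correlations, and linear/exponential
regressions of coupling on disease duration and ophthalmic metrics.

Because patient images in this field are rarely shareable, the package
ships a seeded synthetic-cohort generator with known ground truth
(planted coherence, perfusion effects and an exponential
coupling–duration law), so every stage is testable end to end. It is
intended for methodologists who want a tested, reusable implementation
of this analysis and a phantom to validate it against.

## Worked example

Demographic statistics recomputed exactly from printed cohort
summaries (`python examples/05_table_statistics.py`):

```
age ANOVA:        F(2,83) = 1.86, p = 0.161
sex chi-square:   chi2(2) = 4.72, p = 0.0946
duration t-test:  t(47) = -4.04, p = 1.95e-04
mtDNA Fisher:     exact p = 0.677
```

Age and sex do not differ between groups; disease duration separates
acute from chronic patients sharply; mutation types are independent of
that split.

A full synthetic run (`python examples/03_coupling_and_inference.py`,
6 subjects/group) finds the planted chronic-group effect as a
significant cluster and reports covariate-adjusted contrasts:

```
cluster-forming F threshold: 11.34
significant clusters (FWE p < 0.05): 1
post-hoc ROIs taken from: significant_clusters

Bonferroni-significant pairwise contrasts (covariate-adjusted):
     roi measure group1 group2  estimate         t        p
cluster1   ratio A-LHON C-LHON -0.313652 -8.574403 0.000001
cluster1   ratio C-LHON     HC  0.259850  7.265820 0.000006
cluster1    reho A-LHON C-LHON -0.212019 -5.493470 0.000103
cluster1    reho C-LHON     HC  0.180752  4.790290 0.000353
cluster1     cbf A-LHON C-LHON  0.112228  5.428174 0.000115
cluster1     cbf C-LHON     HC -0.074550 -3.688130 0.002731
```

The chronic group shows a higher coupling ratio than controls driven by
reduced CBF with raised ReHo — the planted pattern. Other examples
cover cohort simulation, single-subject preprocessing/ReHo, and the
duration regressions.

There is also a thin CLI over the same library code:

```bash
nvcoupling simulate -o cohort/ --seed 1 --n-per-group 5
nvcoupling run-all -d cohort/ -o results/ --seed 1
```

which writes statistic maps (NIfTI), cluster/ROI/post-hoc/correlation/
regression tables (TSV) and a run manifest with the config hash and
seed; rerunning with the same manifest reproduces identical outputs.

## Layout

```
src/nvcoupling/
  images.py       containers + NIfTI/TSV/motion-text IO
  synthetic.py    seeded phantom cohort with ground truth
  preproc.py      discard / nuisance regression / band-pass
  reho.py         Kendall's W, ReHo map, scaling, smoothing
  perfusion.py    relative CBF preparation
  coupling.py     ReHo/CBF ratio and ROI summaries
  inference.py    ANCOVA, permutation cluster FWE, post-hoc, scalar tests
  regression.py   residualisation, linear and exponential fits
  pipeline.py     end-to-end orchestration + run manifest
  experiments.py  calibration / recovery replicate studies
  cli.py          thin command-line front end
```

See `docs/methods.md` for the model, assumptions, parameter defaults
and known limitations.
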