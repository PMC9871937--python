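"""Run the full group analysis on a synthetic cohort.

Per subject: preprocess BOLD -> ReHo map; scale + smooth CBF; take the
voxel-wise ReHo/CBF ratio as the neurovascular coupling index.  Then a
voxel-wise three-group ANCOVA (age + gender covariates) with
permutation cluster-extent FWE correction, ROI post-hoc contrasts at
the Bonferroni threshold 0.05/27 = 1.85e-3, and ReHo/CBF-vs-ratio
Pearson correlations.
"""

from nvcoupling import CohortSpec, RunConfig, run_pipeline

spec = CohortSpec(n_per_group={"A-LHON": 6, "C-LHON": 6, "HC": 6}, seed=3)
cfg = RunConfig(synthetic=spec, n_perm=300, seed=3)
res = run_pipeline(cfg)

print(f"cluster-forming F threshold: {res['clusters'].f_threshold:.2f}")
print(f"significant clusters (FWE p < 0.05): {len(res['clusters'].significant)}")
print(f"post-hoc ROIs taken from: {res['roi_source']}\n")

sig = res["posthoc"][res["posthoc"]["significant"]]
cols = ["roi", "measure", "group1", "group2", "estimate", "t", "p"]
print("Bonferroni-significant pairwise contrasts (covariate-adjusted):")
print(sig[cols].to_string(index=False))
print("\nA positive estimate means group1 exceeds group2 after adjusting for")
print("age and gender; the planted pattern is reduced CBF with a raised")
print("coupling ratio in the affected regions.")
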