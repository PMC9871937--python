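"""Simulate a small three-group cohort and inspect what was planted.

The generator produces, for each subject, a 4-D BOLD run with locally
coherent band-limited signal, a 6-column motion trace with occasional
high-motion spikes, and a CBF map with region- and group-specific
perfusion effects, plus one cohort table for the whole study.
"""

from nvcoupling import CohortSpec, simulate_cohort

spec = CohortSpec(
    n_per_group={"A-LHON": 3, "C-LHON": 3, "HC": 3},
    seed=1,
)
cohort = simulate_cohort(spec)

print(f"subjects: {len(cohort.subjects)}, grid: {spec.grid_shape}, "
      f"TR: {spec.tr_s}s, frames: {spec.n_timepoints}")
print("\ncohort table (one row per subject; duration is NA for controls):")
print(cohort.table.to_string(index=False))
print("\nplanted CBF factors (region -> group -> multiplicative effect):")
for region, by_group in cohort.truth.cbf_effect_by_region.items():
    print(f"  {region}: {by_group}")
print("\nA factor below 1 means that region's perfusion is reduced for that")
print("group; coherence (lambda) controls the regional homogeneity ReHo will see.")
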