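"""Clean one BOLD run and compute its ReHo map.

The cleaning chain discards equilibration volumes, regresses nuisance
covariates (trend, WM/CSF means, Friston-24 motion terms, FD > 0.5 mm
spike indicators) and band-pass filters to 0.01-0.10 Hz.  ReHo is
Kendall's W of each voxel with its 26 neighbours, scaled by the brain
global mean and smoothed at 6 mm FWHM.
"""

import numpy as np

from nvcoupling import CohortSpec, generate_bold, make_masks, preprocess, reho_pipeline
from nvcoupling.preproc import framewise_displacement

spec = CohortSpec(n_per_group={"A-LHON": 1, "C-LHON": 1, "HC": 1}, seed=2)
bold, motion = generate_bold(spec, 0)

fd = framewise_displacement(motion)
print(f"frames: {bold.n_timepoints}, FD > 0.5 mm at {np.flatnonzero(fd > 0.5).tolist()}")

clean = preprocess(bold, motion, n_discard=10)
print(f"after discarding 10 volumes: {clean.n_timepoints} frames, "
      f"residual means ~0: {np.abs(clean.data[clean.brain_mask].mean(axis=-1)).max():.2e}")

reho = reho_pipeline(clean)
_, _, _, labels = make_masks(spec)
for rid, name in {1: "cortex", 2: "calcarine", 3: "temporal"}.items():
    print(f"mean scaled ReHo in {name:10s}: {reho.values[labels == rid].mean():.3f}")
print("\nValues are dimensionless (in-brain mean 1); the calcarine region was")
print("planted with higher local coherence, so its ReHo sits above the rest.")
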