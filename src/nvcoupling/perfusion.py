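"""Relative CBF preparation: mask, clip ASL negatives, scale by the
in-brain global mean, smooth.

The output is a dimensionless relative-CBF map with in-mask mean 1
before smoothing (and very close to 1 after mask-renormalised
smoothing).  Inputs are assumed already resampled to the common grid.
"""

from __future__ import annotations

import numpy as np

from .images import VolumeMap
from .reho import gaussian_smooth, scale_by_global_mean


def prepare_cbf(
    raw_cbf: VolumeMap,
    brain_mask: np.ndarray | None = None,
    fwhm_mm=(6.0, 6.0, 6.0),
) -> VolumeMap:
    """Mask -> clip negatives to 0 -> global-mean scale -> smooth.

    Negative raw values (ASL noise) are clipped to zero and their count
    recorded in ``meta['n_clipped_negative']``.  An all-zero in-mask map
    is rejected.
    """
    mask = raw_cbf.mask if brain_mask is None else np.asarray(brain_mask, bool)
    if mask.shape != raw_cbf.shape:
        raise ValueError("brain mask shape does not match CBF grid")
    values = np.where(mask, raw_cbf.values, 0.0)
    n_neg = int(np.count_nonzero(values[mask] < 0))
    values = np.clip(values, 0.0, None)
    vol = VolumeMap(
        values=values,
        mask=mask,
        voxel_size_mm=raw_cbf.voxel_size_mm,
        meta={**raw_cbf.meta, "kind": "cbf", "n_clipped_negative": n_neg},
    )
    if vol.in_mask_mean() <= 0:
        raise ValueError("in-mask CBF is all zero; cannot scale")
    return gaussian_smooth(scale_by_global_mean(vol), fwhm_mm)
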