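"""Neurovascular coupling index: voxel-wise ReHo/CBF ratio and ROI
summaries.

Because both inputs are globally scaled, the ratio is dimensionless and
invariant to any positive rescaling of the raw ReHo or CBF maps.  A
small epsilon guards against near-zero denominators that mask-edge
smoothing can produce.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .images import VolumeMap

DEFAULT_EPSILON = 0.05


def compute_ratio(
    reho: VolumeMap, cbf: VolumeMap, epsilon: float = DEFAULT_EPSILON
) -> VolumeMap:
    """ReHo/CBF where CBF >= epsilon; other voxels are excluded.

    The returned map's ``meta['valid_mask']`` marks voxels where the
    ratio is defined; excluded-voxel count is in ``meta['n_below_eps']``.
    """
    if reho.shape != cbf.shape:
        raise ValueError("ReHo and CBF grids do not match")
    if not np.array_equal(reho.mask, cbf.mask):
        raise ValueError("ReHo and CBF masks do not match")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    valid = reho.mask & (cbf.values >= epsilon)
    values = np.zeros_like(reho.values)
    values[valid] = reho.values[valid] / cbf.values[valid]
    return VolumeMap(
        values=values,
        mask=reho.mask,
        voxel_size_mm=reho.voxel_size_mm,
        meta={
            "kind": "ratio",
            "epsilon": epsilon,
            "valid_mask": valid,
            "n_below_eps": int(np.count_nonzero(reho.mask & ~valid)),
        },
    )


def _roi_mean(vol: VolumeMap, roi: np.ndarray) -> float:
    valid = vol.meta.get("valid_mask", vol.mask)
    sel = roi & valid
    if not sel.any():
        return float("nan")
    return float(vol.values[sel].mean())


def summarize_rois(
    subject_maps: dict[str, dict[str, VolumeMap]],
    labels: np.ndarray,
    roi_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per subject x ROI mean ratio / ReHo / CBF.

    Parameters
    ----------
    subject_maps : dict subject -> {'ratio': ..., 'reho': ..., 'cbf': ...}
    labels : integer label volume; 0 is background (no ROI)
    roi_names : optional label -> name mapping for readable output

    ROI means are taken over ROI voxels where each map is defined (the
    ratio's valid mask for the ratio, the brain mask otherwise); an
    empty intersection yields NaN.
    """
    labels = np.asarray(labels)
    roi_ids = [int(v) for v in np.unique(labels) if v != 0]
    rows = []
    for subject, maps in subject_maps.items():
        for rid in roi_ids:
            roi = labels == rid
            rows.append(
                {
                    "subject": subject,
                    "roi": (roi_names or {}).get(rid, f"roi{rid}"),
                    "ratio": _roi_mean(maps["ratio"], roi),
                    "reho": _roi_mean(maps["reho"], roi),
                    "cbf": _roi_mean(maps["cbf"], roi),
                }
            )
    return pd.DataFrame(rows)
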