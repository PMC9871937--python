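"""Regional homogeneity (ReHo): Kendall's coefficient of concordance of
each voxel's time series with its 26 neighbours, global-mean scaling and
mask-aware Gaussian smoothing.

Kendall's W here follows the original ReHo formulation: midranks for
ties and no tie-correction term in the denominator,

    W = 12 * sum_i (R_i - K(n+1)/2)^2 / (K^2 (n^3 - n)),

where K series are ranked over n timepoints and R_i is the rank sum at
timepoint i.  W is 1 for perfectly concordant series and has expectation
1/K for independent ones.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .images import BoldSeries, VolumeMap

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


def kendalls_w(series_block: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series over n timepoints.

    Parameters
    ----------
    series_block : ndarray, shape (K, n)

    Raises
    ------
    ValueError
        If K < 2, n < 2, or any series is constant (W undefined).
    """
    block = np.asarray(series_block, float)
    if block.ndim != 2:
        raise ValueError("series_block must be 2-D (K, n)")
    K, n = block.shape
    if K < 2 or n < 2:
        raise ValueError("need at least 2 series and 2 timepoints")
    if np.any(np.ptp(block, axis=1) == 0):
        raise ValueError("constant series: concordance undefined")
    ranks = rankdata(block, axis=1)  # midranks for ties
    R = ranks.sum(axis=0)
    S = float(((R - K * (n + 1) / 2.0) ** 2).sum())
    return 12.0 * S / (K**2 * (n**3 - n))


def _rank_along_last(block: np.ndarray) -> np.ndarray:
    """Ranks along the last axis; midranks when ties are present.

    Uses a double argsort (ordinal ranks) on the common tie-free path
    and falls back to midranks only when ties exist.
    """
    order = np.argsort(block, axis=-1, kind="stable")
    srt = np.take_along_axis(block, order, axis=-1)
    if np.any(np.diff(srt, axis=-1) == 0):
        return rankdata(block, axis=-1)
    ranks = np.empty_like(block)
    np.put_along_axis(
        ranks, order,
        np.broadcast_to(np.arange(1.0, block.shape[-1] + 1.0), block.shape),
        axis=-1,
    )
    return ranks


def _shift3(arr: np.ndarray, dx: int, dy: int, dz: int) -> np.ndarray:
    """Shift the first three axes by (dx, dy, dz), zero-filling the border."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for d, size in zip((dx, dy, dz), arr.shape[:3]):
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def compute_reho_map(bold: BoldSeries) -> VolumeMap:
    """ReHo map: Kendall's W over each voxel's 3x3x3 neighbourhood.

    In-mask voxels whose full 27-voxel neighbourhood is in-mask use all
    27 series; voxels at the mask edge use the K < 27 available in-mask
    neighbours (flagged in ``meta['reduced_k_mask']``).  Neighbourhoods
    containing a constant series, or with K < 2, are set to 0 and
    flagged in ``meta['undefined_mask']``.  Out-of-mask voxels are 0.
    """
    data = bold.data
    mask = bold.brain_mask
    n = bold.n_timepoints
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    if min(data.shape[:3]) < 3:
        raise ValueError("grid too small for a 3x3x3 neighbourhood")

    ranks = np.zeros(data.shape)
    ranks[mask] = _rank_along_last(data[mask])
    const = np.zeros(mask.shape, bool)
    const[mask] = np.ptp(data[mask], axis=-1) == 0
    maskf = mask.astype(float)

    rank_sum = np.zeros(data.shape)
    k_map = np.zeros(mask.shape)
    bad = np.zeros(mask.shape, bool)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                rank_sum += _shift3(ranks, dx, dy, dz)
                k_map += _shift3(maskf, dx, dy, dz)
                bad |= _shift3(const, dx, dy, dz)

    K = k_map
    valid = mask & (K >= 2) & ~bad
    values = np.zeros(mask.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = ((rank_sum - K[..., None] * (n + 1) / 2.0) ** 2).sum(axis=-1)
        W = 12.0 * S / (K**2 * (n**3 - n))
    values[valid] = W[valid]
    return VolumeMap(
        values=values,
        mask=mask,
        voxel_size_mm=bold.voxel_size_mm,
        meta={
            "kind": "reho",
            "scaled": False,
            "smoothed": False,
            "reduced_k_mask": mask & (K < 27),
            "undefined_mask": mask & ~valid,
        },
    )


def scale_by_global_mean(vol: VolumeMap) -> VolumeMap:
    """Divide every in-mask value by the in-mask mean (global scaling)."""
    mean = vol.in_mask_mean()
    if mean <= 0:
        raise ValueError("in-mask mean must be positive for global scaling")
    values = vol.values.copy()
    values[vol.mask] = values[vol.mask] / mean
    return vol.copy_with(values=values, scaled=True, global_mean=mean)


def gaussian_smooth(vol: VolumeMap, fwhm_mm=(6.0, 6.0, 6.0)) -> VolumeMap:
    """Mask-renormalised separable Gaussian smoothing.

    sigma per axis is fwhm / voxel_size / (2 sqrt(2 ln 2)) in voxel
    units.  The kernel is renormalised over in-mask support so zeros
    outside the mask do not bleed in; a constant in-mask map is left
    unchanged.  ``fwhm_mm = 0`` is the identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm == 0):
        return vol.copy_with(smoothed=True, fwhm_mm=tuple(fwhm))
    sigma_vox = fwhm / np.asarray(vol.voxel_size_mm) / FWHM_TO_SIGMA
    maskf = vol.mask.astype(float)
    num = ndimage.gaussian_filter(vol.values * maskf, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(maskf, sigma_vox, mode="constant")
    values = np.zeros_like(vol.values)
    inside = vol.mask & (den > 0)
    values[inside] = num[inside] / den[inside]
    return vol.copy_with(values=values, smoothed=True, fwhm_mm=tuple(fwhm))


def reho_pipeline(bold: BoldSeries, fwhm_mm=(6.0, 6.0, 6.0)) -> VolumeMap:
    """compute -> scale by global mean -> smooth, the standard ReHo chain."""
    return gaussian_smooth(scale_by_global_mean(compute_reho_map(bold)), fwhm_mm)
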