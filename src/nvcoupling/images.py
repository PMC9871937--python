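"""In-memory containers for volumetric data and their on-disk formats.

All images live on a common grid (the study space, 2 mm isotropic by
default); no registration is performed here.  NIfTI-1 is the on-disk
format for volumes, whitespace-delimited text for motion traces, and TSV
for the cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "subject",
    "group",
    "age",
    "gender",
    "duration_months",
    "MD",
    "MS",
    "LV",
    "RNFL",
]

GROUPS = ("A-LHON", "C-LHON", "HC")


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


@dataclass
class VolumeMap:
    """A 3-D scalar map (ReHo, CBF, ratio, F statistic ...) with its mask.

    Parameters
    ----------
    values : ndarray, shape (x, y, z)
        Scalar values; voxels outside ``mask`` are conventionally 0.
    mask : ndarray of bool, same shape
        Voxels on which the map is defined.
    voxel_size_mm : 3-tuple
        Physical voxel edge lengths in mm.
    meta : dict
        Provenance flags (scaled, smoothed, fwhm_mm, QC masks ...).
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = _as_bool(self.mask)
        if self.values.ndim != 3:
            raise ValueError("VolumeMap.values must be 3-D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def in_mask_mean(self) -> float:
        return float(self.values[self.mask].mean())

    def copy_with(self, values: np.ndarray | None = None, **meta) -> "VolumeMap":
        new = VolumeMap(
            values=self.values.copy() if values is None else np.asarray(values, float),
            mask=self.mask.copy(),
            voxel_size_mm=self.voxel_size_mm,
            meta={**self.meta, **meta},
        )
        return new


@dataclass
class BoldSeries:
    """A 4-D BOLD run (x, y, z, t) with its acquisition and tissue masks."""

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_mask: np.ndarray | None = None
    wm_mask: np.ndarray | None = None
    csf_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldSeries.data must be 4-D (x, y, z, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("BoldSeries needs at least 2 timepoints")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        grid = self.data.shape[:3]
        if self.brain_mask is None:
            self.brain_mask = np.ones(grid, bool)
        self.brain_mask = _as_bool(self.brain_mask)
        for name in ("wm_mask", "csf_mask"):
            m = getattr(self, name)
            if m is None:
                m = np.zeros(grid, bool)
            m = _as_bool(m)
            if m.shape != grid:
                raise ValueError(f"{name} shape does not match data grid")
            if np.any(m & ~self.brain_mask):
                raise ValueError(f"{name} must lie inside the brain mask")
            setattr(self, name, m)
        if self.brain_mask.shape != grid:
            raise ValueError("brain_mask shape does not match data grid")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MotionTrace:
    """Rigid-body motion parameters, one row per volume.

    Columns: x, y, z translations (mm) then pitch, roll, yaw rotations
    (radians) — the convention written by the motion text files here.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("MotionTrace.params must have 6 columns")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


# ---------------------------------------------------------------------------
# NIfTI / text IO


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    return aff


def save_volume(vol: VolumeMap, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.voxel_size_mm))
    img.to_filename(str(path))


def load_volume(path: str | Path, mask: np.ndarray | None = None) -> VolumeMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    if mask is None:
        mask = np.ones(data.shape, bool)
    return VolumeMap(values=data, mask=mask, voxel_size_mm=vox)


def save_mask(mask: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
    img.to_filename(str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_labels(labels: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.astype(np.int16), _affine(voxel_size_mm))
    img.to_filename(str(path))


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(int)


def save_bold(bold: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(bold.voxel_size_mm))
    img.header.set_zooms((*bold.voxel_size_mm, bold.tr_s))
    img.to_filename(str(path))


def load_bold(
    path: str | Path,
    brain_mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    tr_s: float | None = None,
) -> BoldSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if tr_s is None else float(tr_s)
    return BoldSeries(
        data=np.asarray(img.dataobj, dtype=float),
        tr_s=tr,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        brain_mask=brain_mask,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
    )


def save_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), motion.params, fmt="%.8f")


def load_motion(path: str | Path) -> MotionTrace:
    return MotionTrace(params=np.loadtxt(str(path), ndmin=2))


def save_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False, na_rep="NA", float_format="%.6g")


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", na_values=["NA"])
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df
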