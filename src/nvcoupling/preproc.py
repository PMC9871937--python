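"""Resting-state BOLD cleaning: volume discarding, nuisance regression,
band-pass filtering.

The chain expects spatially aligned input (simulated data is generated
in common space; real data must be realigned/normalised upstream) and
runs, in order: discard initial volumes -> nuisance covariate regression
(intercept, linear trend, WM/CSF mean signals, Friston-24 motion terms,
per-frame spike indicators for frames with framewise displacement above
threshold) -> ideal band-pass filter.  Voxels outside the brain mask are
never modified and never contribute to the WM/CSF mean signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import BoldSeries, MotionTrace

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_BAND_HZ = (0.01, 0.10)


def discard_initial_volumes(
    bold: BoldSeries, motion: MotionTrace, n_discard: int
) -> tuple[BoldSeries, MotionTrace]:
    """Drop the first ``n_discard`` frames of BOLD and motion in lockstep.

    Raises
    ------
    ValueError
        If ``n_discard`` would leave fewer than 2 frames.
    """
    if motion.n_frames != bold.n_timepoints:
        raise ValueError("motion rows must match BOLD timepoints")
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if bold.n_timepoints - n_discard < 2:
        raise ValueError(
            f"discarding {n_discard} of {bold.n_timepoints} frames leaves "
            "fewer than 2 volumes"
        )
    if n_discard == 0:
        return bold, motion
    out = BoldSeries(
        data=bold.data[..., n_discard:].copy(),
        tr_s=bold.tr_s,
        voxel_size_mm=bold.voxel_size_mm,
        brain_mask=bold.brain_mask,
        wm_mask=bold.wm_mask,
        csf_mask=bold.csf_mask,
    )
    return out, MotionTrace(params=motion.params[n_discard:].copy())


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power framewise displacement: FD_i = sum |d trans| + r * sum |d rot|.

    FD of the first frame is 0 by convention.  Rotations (radians) are
    converted to arc length on a sphere of ``head_radius_mm``.
    """
    if motion.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    d = np.abs(np.diff(motion.params, axis=0))
    fd = np.zeros(motion.n_frames)
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def build_friston24(motion: MotionTrace) -> np.ndarray:
    """Friston-24 motion regressors: [p, p^2, p(t-1), p(t-1)^2] per parameter.

    The lagged terms use 0 at the first frame.  Returns a (t, 24) block
    ordered as 6 params, 6 squares, 6 lags, 6 lagged squares.
    """
    p = motion.params
    lag = np.zeros_like(p)
    lag[1:] = p[:-1]
    return np.hstack([p, p**2, lag, lag**2])


def build_spike_regressors(fd: np.ndarray, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> np.ndarray:
    """One indicator column per frame with FD above threshold.

    Returns a (t, n_spikes) array (possibly with 0 columns).
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    fd = np.asarray(fd, float)
    frames = np.flatnonzero(fd > threshold_mm)
    cols = np.zeros((fd.size, frames.size))
    cols[frames, np.arange(frames.size)] = 1.0
    return cols


@dataclass
class NuisanceDesign:
    """Nuisance regressor matrix with column labels."""

    matrix: np.ndarray  # (t, k)
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix / label mismatch")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def build_nuisance_design(
    bold: BoldSeries,
    motion: MotionTrace,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
) -> NuisanceDesign:
    """Assemble intercept + trend + WM/CSF means + Friston-24 + spikes.

    All-zero columns (e.g. motionless traces) and duplicated spike
    columns are pruned; a design that is still rank-deficient afterwards
    is rejected.
    """
    t = bold.n_timepoints
    if motion.n_frames != t:
        raise ValueError("motion rows must match BOLD timepoints")
    cols: list[np.ndarray] = []
    labels: list[str] = []

    cols.append(np.ones(t))
    labels.append("intercept")
    trend = np.linspace(-1.0, 1.0, t)
    cols.append(trend)
    labels.append("linear_trend")

    for name, mask in (("wm_mean", bold.wm_mask), ("csf_mean", bold.csf_mask)):
        if mask.any():
            sig = bold.data[mask].mean(axis=0)
            sig = sig - sig.mean()
            cols.append(sig)
            labels.append(name)

    f24 = build_friston24(motion)
    f24 = f24 - f24.mean(axis=0)  # demeaned so intercept stays interpretable
    for j in range(24):
        cols.append(f24[:, j])
        labels.append(f"friston24_{j}")

    fd = framewise_displacement(motion, head_radius_mm)
    spikes = build_spike_regressors(fd, fd_threshold_mm)
    for j in range(spikes.shape[1]):
        cols.append(spikes[:, j])
        labels.append(f"spike_{int(np.flatnonzero(spikes[:, j])[0])}")

    X = np.column_stack(cols)
    # greedy rank-based pruning: drop all-zero columns and any column
    # linearly dependent on earlier ones (e.g. spike indicators already
    # spanned by step-like motion terms); left-to-right order makes the
    # choice deterministic and the design full rank by construction
    keep: list[int] = []
    Q = np.empty((t, 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        norm = np.linalg.norm(col)
        if norm == 0:
            continue
        resid = col - Q @ (Q.T @ col)
        if np.linalg.norm(resid) <= 1e-10 * norm:
            continue
        Q = np.column_stack([Q, resid / np.linalg.norm(resid)])
        keep.append(j)
    X = X[:, keep]
    labels = [labels[j] for j in keep]

    if X.shape[1] >= t:
        raise ValueError(
            f"nuisance design has {X.shape[1]} columns for only {t} frames"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "nuisance design is rank-deficient after pruning; "
            f"columns: {labels}"
        )
    return NuisanceDesign(matrix=X, labels=labels)


def regress_nuisance(bold: BoldSeries, design: NuisanceDesign) -> BoldSeries:
    """Replace each in-mask voxel series by its least-squares residual."""
    if design.n_frames != bold.n_timepoints:
        raise ValueError("design rows must match BOLD timepoints")
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    data = bold.data.copy()
    Y = data[bold.brain_mask].T  # (t, V)
    Q, _ = np.linalg.qr(X)
    data[bold.brain_mask] = (Y - Q @ (Q.T @ Y)).T
    return BoldSeries(
        data=data,
        tr_s=bold.tr_s,
        voxel_size_mm=bold.voxel_size_mm,
        brain_mask=bold.brain_mask,
        wm_mask=bold.wm_mask,
        csf_mask=bold.csf_mask,
    )


def bandpass_filter(
    bold: BoldSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> BoldSeries:
    """Ideal rectangular band-pass in the frequency domain.

    Fourier coefficients with frequency in the closed interval
    [low_hz, high_hz] are retained, all others (including DC) are
    zeroed; no padding is applied.  Only in-mask voxels are filtered.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist}")
    t = bold.n_timepoints
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    keep[0] = False  # DC always removed
    data = bold.data.copy()
    Y = data[bold.brain_mask]
    spec = np.fft.rfft(Y, axis=-1)
    spec[:, ~keep] = 0.0
    data[bold.brain_mask] = np.fft.irfft(spec, n=t, axis=-1)
    return BoldSeries(
        data=data,
        tr_s=bold.tr_s,
        voxel_size_mm=bold.voxel_size_mm,
        brain_mask=bold.brain_mask,
        wm_mask=bold.wm_mask,
        csf_mask=bold.csf_mask,
    )


def preprocess(
    bold: BoldSeries,
    motion: MotionTrace,
    n_discard: int = 10,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
) -> BoldSeries:
    """Full cleaning chain: discard -> nuisance regression -> band-pass."""
    bold, motion = discard_initial_volumes(bold, motion, n_discard)
    design = build_nuisance_design(bold, motion, fd_threshold_mm, head_radius_mm)
    bold = regress_nuisance(bold, design)
    return bandpass_filter(bold, *band_hz)
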