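"""Seeded synthetic three-group cohort (BOLD + motion + CBF + masks +
cohort table) with known ground truth.

The generator emulates, in a desk-scale phantom, the features the
analysis must detect: band-limited locally coherent BOLD signal whose
mixing weight lambda controls true regional homogeneity; WM/CSF-loaded
drift and motion-locked intensity spikes for the nuisance stage to
remove; CBF maps with region- and group-specific multiplicative
effects; and a cohort table whose planted region coupling follows an
exponential disease-duration law Y = a*exp(b*x) + c.

Default effect directions mirror the study pattern: a "calcarine"
region with reduced CBF but unchanged coherence in both patient groups,
and a "temporal" region with reduced CBF and raised coherence in the
chronic group only.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .images import (
    BoldSeries,
    COHORT_COLUMNS,
    GROUPS,
    MotionTrace,
    VolumeMap,
    save_bold,
    save_cohort_table,
    save_labels,
    save_mask,
    save_motion,
    save_volume,
)

REGION_NAMES = {1: "cortex", 2: "calcarine", 3: "temporal"}

_DEF_COHERENCE = {
    "cortex": {"A-LHON": 0.30, "C-LHON": 0.30, "HC": 0.30},
    "calcarine": {"A-LHON": 0.50, "C-LHON": 0.50, "HC": 0.50},
    "temporal": {"A-LHON": 0.40, "C-LHON": 0.55, "HC": 0.40},
}
_DEF_CBF_EFFECT = {
    "cortex": {"A-LHON": 1.0, "C-LHON": 1.0, "HC": 1.0},
    "calcarine": {"A-LHON": 0.80, "C-LHON": 0.80, "HC": 1.0},
    "temporal": {"A-LHON": 1.0, "C-LHON": 0.75, "HC": 1.0},
}

# Group-conditional clinical distributions (mean, sd), mirroring the
# cohort summaries the design matrices must cope with.
_CLINICAL = {
    "MD": {"A-LHON": (13.35, 9.27), "C-LHON": (18.10, 7.99), "HC": (1.49, 1.11)},
    "MS": {"A-LHON": (15.83, 8.07), "C-LHON": (10.92, 8.15), "HC": (27.60, 1.18)},
    "LV": {"A-LHON": (24.91, 25.29), "C-LHON": (37.14, 25.27), "HC": (4.05, 1.97)},
    "RNFL": {"A-LHON": (104.53, 25.21), "C-LHON": (60.20, 11.08), "HC": (100.23, 6.99)},
}
_MALE_FRACTION = {"A-LHON": 0.90, "C-LHON": 0.62, "HC": 0.73}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    lambda (coherence) weights are per region per group in [0, 1]; CBF
    effects are positive multiplicative factors.  ``duration_model``
    holds (a, b, c) of the planted exponential coupling-duration law
    for the temporal region, Y = a*exp(b*duration_months) + c.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"A-LHON": 20, "C-LHON": 29, "HC": 37}
    )
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_timepoints: int = 120
    tr_s: float = 2.0
    coherence_by_region: dict = field(default_factory=lambda: {
        r: dict(g) for r, g in _DEF_COHERENCE.items()
    })
    cbf_effect_by_region: dict = field(default_factory=lambda: {
        r: dict(g) for r, g in _DEF_CBF_EFFECT.items()
    })
    duration_model: tuple[float, float, float] = (0.08, 0.006, 1.05)
    noise_sd: float = 1.0
    cbf_noise_sd: float = 0.05
    coupling_noise_sd: float = 0.08
    spike_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if min(self.grid_shape) < 3:
            raise ValueError("grid too small for a 3x3x3 neighbourhood")
        for region, by_group in self.coherence_by_region.items():
            for g, lam in by_group.items():
                if not (0.0 <= lam <= 1.0):
                    raise ValueError(f"lambda for {region}/{g} outside [0, 1]")
        for region, by_group in self.cbf_effect_by_region.items():
            for g, fac in by_group.items():
                if fac <= 0:
                    raise ValueError(f"CBF factor for {region}/{g} must be > 0")
        # room for intercept+trend+WM+CSF+24 motion terms and a margin
        if self.n_timepoints <= 28 + 10:
            raise ValueError("n_timepoints too small for the nuisance design")
        if not (0.0 <= self.spike_rate < 1.0):
            raise ValueError("spike_rate must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group[g] for g in GROUPS)

    def group_of(self, subject_index: int) -> str:
        if not (0 <= subject_index < self.n_subjects):
            raise ValueError("subject_index outside cohort")
        edge = 0
        for g in GROUPS:
            edge += self.n_per_group[g]
            if subject_index < edge:
                return g
        raise AssertionError

    def subject_id(self, subject_index: int) -> str:
        return f"sub{subject_index:03d}"

    def with_(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted: labels, per-region/group effects, durations,
    and the per-subject planted temporal-region coupling."""

    region_labels: np.ndarray
    coherence_by_region: dict
    cbf_effect_by_region: dict
    duration_model: tuple[float, float, float]
    durations: pd.Series  # indexed by subject id, NaN for HC
    planted_coupling: pd.Series  # indexed by subject id, NaN for HC


# ---------------------------------------------------------------------------
# geometry


def make_masks(spec: CohortSpec):
    """Deterministic phantom geometry: ellipsoid brain, central WM and
    CSF blocks, posterior 'calcarine' and lateral 'temporal' regions.

    Returns (brain, wm, csf, labels); labels cover the whole brain mask
    (1 = unspecialised cortex, 2 = calcarine, 3 = temporal).
    """
    nx, ny, nz = spec.grid_shape
    x, y, z = np.indices(spec.grid_shape)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    brain = (
        ((x - cx) / (0.44 * nx)) ** 2
        + ((y - cy) / (0.44 * ny)) ** 2
        + ((z - cz) / (0.42 * nz)) ** 2
    ) <= 1.0

    def block(xs, ys, zs):
        m = np.zeros(spec.grid_shape, bool)
        m[xs, ys, zs] = True
        return m & brain

    wm = block(
        slice(int(0.42 * nx), int(0.58 * nx)),
        slice(int(0.42 * ny), int(0.58 * ny)),
        slice(int(0.40 * nz), int(0.60 * nz)),
    )
    csf = block(
        slice(int(0.60 * nx), int(0.72 * nx)),
        slice(int(0.42 * ny), int(0.58 * ny)),
        slice(int(0.40 * nz), int(0.60 * nz)),
    )
    # planted regions: a small brain fraction (so global-mean scaling is
    # not contaminated by the planted effects) yet compact and several
    # smoothing-kernel widths across (so smoothing does not wash the
    # effect out of the ROI mean)
    calcarine = block(
        slice(int(0.33 * nx), int(0.60 * nx)),
        slice(int(0.12 * ny), int(0.38 * ny)),
        slice(int(0.33 * nz), int(0.65 * nz)),
    )
    temporal = block(
        slice(int(0.14 * nx), int(0.30 * nx)),
        slice(int(0.46 * ny), int(0.64 * ny)),
        slice(int(0.38 * nz), int(0.58 * nz)),
    )
    calcarine &= ~(wm | csf)
    temporal &= ~(wm | csf | calcarine)
    labels = np.zeros(spec.grid_shape, int)
    labels[brain] = 1
    labels[calcarine] = 2
    labels[temporal] = 3
    return brain, wm, csf, labels


# ---------------------------------------------------------------------------
# signal synthesis


def _band_limited(rng, n_t, tr_s, low=0.01, high=0.10, size=1) -> np.ndarray:
    """Unit-variance signals with support only on [low, high] Hz bins.

    Synthesised in the frequency domain with random phases so the true
    signal survives the band-pass stage unchanged.
    """
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    keep[0] = False
    spec = np.zeros((size, freqs.size), complex)
    nk = int(keep.sum())
    amp = rng.standard_normal((size, nk)) + 1j * rng.standard_normal((size, nk))
    spec[:, keep] = amp
    sig = np.fft.irfft(spec, n=n_t, axis=-1)
    # DC is zero, so the mean is exactly 0 and sd reduces to an RMS
    sd = np.sqrt(np.einsum("ij,ij->i", sig, sig) / n_t)[:, None]
    sd[sd == 0] = 1.0
    return sig / sd


def _rng(spec: CohortSpec, *stream) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


def generate_bold(spec: CohortSpec, subject_index: int) -> tuple[BoldSeries, MotionTrace]:
    """One subject's 4-D BOLD run plus its motion trace.

    Each voxel series is lambda * (shared regional band-limited signal)
    + (1 - lambda) * independent band-limited noise, scaled by
    ``noise_sd`` on a baseline of 100, plus a WM/CSF-loaded slow drift
    and additive global intensity jumps co-timed with motion steps that
    push FD above 0.5 mm exactly at the planted spike frames.
    """
    group = spec.group_of(subject_index)
    brain, wm, csf, labels = make_masks(spec)
    n_t = spec.n_timepoints
    rng = _rng(spec, 1, subject_index)

    region_sig = {
        rid: _band_limited(rng, n_t, spec.tr_s)[0] for rid in REGION_NAMES
    }
    data = np.zeros((*spec.grid_shape, n_t))
    vox_idx = np.flatnonzero(brain.ravel())
    noise = _band_limited(rng, n_t, spec.tr_s, size=vox_idx.size)
    lam_vol = np.zeros(spec.grid_shape)
    for rid, rname in REGION_NAMES.items():
        lam_vol[labels == rid] = spec.coherence_by_region[rname][group]
    # WM/CSF carry no coherent BOLD signal, only noise and drift —
    # otherwise their mean regressors would remove gray-matter signal
    lam_vol[wm | csf] = 0.0
    lam = lam_vol.ravel()[vox_idx][:, None]
    shared = np.zeros((vox_idx.size, n_t))
    lab_flat = labels.ravel()[vox_idx]
    for rid in REGION_NAMES:
        shared[lab_flat == rid] = region_sig[rid]
    series = spec.noise_sd * (lam * shared + (1.0 - lam) * noise)

    # slow drift, loaded on WM/CSF (what the mean-signal regressors remove)
    t_ax = np.arange(n_t)
    drift = 0.6 * (t_ax - t_ax.mean()) / n_t + 0.5 * np.sin(
        2 * np.pi * 0.004 * spec.tr_s * t_ax + rng.uniform(0, 2 * np.pi)
    )
    wmcsf_flat = (wm | csf).ravel()[vox_idx]
    drift_gain = np.where(wmcsf_flat, 2.0, 0.4)[:, None] * spec.noise_sd
    series = series + drift_gain * drift[None, :]

    # motion: small jitter plus sustained steps at planted spike frames
    motion = np.zeros((n_t, 6))
    motion[:, :3] = rng.normal(0.0, 0.01, (n_t, 3))
    motion[:, 3:] = rng.normal(0.0, 2e-4, (n_t, 3))
    spikes = np.flatnonzero(rng.random(n_t - 1) < spike_rate_eff(spec)) + 1
    sign = 1.0
    for f in spikes:
        motion[f:, 0] += sign * 0.8
        sign = -sign
        series[:, f] += 3.0 * spec.noise_sd  # motion-locked intensity jump

    series += 100.0
    flat = data.reshape(-1, n_t)
    flat[vox_idx] = series
    bold = BoldSeries(
        data=data,
        tr_s=spec.tr_s,
        voxel_size_mm=spec.voxel_size_mm,
        brain_mask=brain,
        wm_mask=wm,
        csf_mask=csf,
    )
    return bold, MotionTrace(params=motion)


def spike_rate_eff(spec: CohortSpec) -> float:
    return spec.spike_rate


def generate_cbf(spec: CohortSpec, subject_index: int) -> VolumeMap:
    """One subject's raw CBF map: smooth positive baseline x region/group
    factor x mild multiplicative subject noise; 0 outside the brain."""
    from scipy import ndimage

    group = spec.group_of(subject_index)
    brain, _, _, labels = make_masks(spec)
    base_rng = _rng(spec, 2)  # baseline shared by all subjects
    base_field = ndimage.gaussian_filter(
        base_rng.standard_normal(spec.grid_shape), 2.0, mode="constant"
    )
    sd = base_field.std() or 1.0
    baseline = 55.0 * (1.0 + 0.25 * base_field / sd)
    baseline = np.clip(baseline, 10.0, None)

    rng = _rng(spec, 3, subject_index)
    subj_field = ndimage.gaussian_filter(
        rng.standard_normal(spec.grid_shape), 2.0, mode="constant"
    )
    fsd = subj_field.std() or 1.0
    noise = np.exp(spec.cbf_noise_sd * subj_field / fsd) * np.exp(
        rng.normal(0.0, spec.cbf_noise_sd / 2.0)
    )
    factor = np.ones(spec.grid_shape)
    for rid, rname in REGION_NAMES.items():
        factor[labels == rid] = spec.cbf_effect_by_region[rname][group]
    values = np.where(brain, baseline * factor * noise, 0.0)
    return VolumeMap(
        values=values,
        mask=brain,
        voxel_size_mm=spec.voxel_size_mm,
        meta={"kind": "cbf_raw", "group": group},
    )


def generate_cohort_table(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort table (demographics, durations, clinical metrics) plus the
    planted exponential coupling-duration values for the temporal region.

    Durations: acute patients <= 12 months, chronic > 12 months; healthy
    controls carry the NA sentinel.
    """
    rng = _rng(spec, 4)
    a, b, c = spec.duration_model
    rows = []
    for i in range(spec.n_subjects):
        g = spec.group_of(i)
        age = float(np.round(rng.uniform(10.0, 55.0), 1))
        gender = "M" if rng.random() < _MALE_FRACTION[g] else "F"
        if g == "A-LHON":
            dur = float(np.round(min(12.0, 0.7 + rng.exponential(4.0)), 1))
        elif g == "C-LHON":
            dur = float(np.round(min(422.0, 12.0 + rng.exponential(110.0)), 1))
        else:
            dur = np.nan
        clin = {
            k: float(np.round(max(0.0, rng.normal(*v[g])), 2))
            for k, v in _CLINICAL.items()
        }
        if np.isnan(dur):
            coupling = np.nan
        else:
            coupling = a * np.exp(b * dur) + c + rng.normal(0.0, spec.coupling_noise_sd)
        rows.append(
            {
                "subject": spec.subject_id(i),
                "group": g,
                "age": age,
                "gender": gender,
                "duration_months": dur,
                **clin,
                "_coupling": coupling,
            }
        )
    df = pd.DataFrame(rows)
    coupling = df.set_index("subject")["_coupling"]
    table = df[COHORT_COLUMNS].copy()
    _, _, _, labels = make_masks(spec)
    truth = GroundTruth(
        region_labels=labels,
        coherence_by_region={r: dict(g) for r, g in spec.coherence_by_region.items()},
        cbf_effect_by_region={r: dict(g) for r, g in spec.cbf_effect_by_region.items()},
        duration_model=spec.duration_model,
        durations=table.set_index("subject")["duration_months"],
        planted_coupling=coupling,
    )
    return table, truth


# ---------------------------------------------------------------------------
# whole-cohort containers


@dataclass
class SubjectData:
    subject: str
    group: str
    bold: BoldSeries
    motion: MotionTrace
    cbf: VolumeMap


@dataclass
class Cohort:
    spec: CohortSpec
    table: pd.DataFrame
    truth: GroundTruth
    subjects: list[SubjectData]
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full in-memory cohort (table + per-subject images)."""
    table, truth = generate_cohort_table(spec)
    brain, wm, csf, _ = make_masks(spec)
    subjects = []
    for i in range(spec.n_subjects):
        bold, motion = generate_bold(spec, i)
        cbf = generate_cbf(spec, i)
        subjects.append(
            SubjectData(
                subject=spec.subject_id(i),
                group=spec.group_of(i),
                bold=bold,
                motion=motion,
                cbf=cbf,
            )
        )
    return Cohort(
        spec=spec,
        table=table,
        truth=truth,
        subjects=subjects,
        brain_mask=brain,
        wm_mask=wm,
        csf_mask=csf,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort to disk: NIfTI volumes, motion text, TSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vx = cohort.spec.voxel_size_mm
    save_mask(cohort.brain_mask, vx, out / "brain_mask.nii.gz")
    save_mask(cohort.wm_mask, vx, out / "wm_mask.nii.gz")
    save_mask(cohort.csf_mask, vx, out / "csf_mask.nii.gz")
    save_labels(cohort.truth.region_labels, vx, out / "region_labels.nii.gz")
    save_cohort_table(cohort.table, out / "cohort.tsv")
    for s in cohort.subjects:
        save_bold(s.bold, out / f"{s.subject}_bold.nii.gz")
        save_motion(s.motion, out / f"{s.subject}_motion.txt")
        save_volume(s.cbf, out / f"{s.subject}_cbf.nii.gz")
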