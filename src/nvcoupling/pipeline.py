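"""End-to-end orchestration: (simulate | load) -> preprocess -> ReHo ->
CBF -> coupling -> group inference -> clinical regression.

``run_pipeline`` is the single entry point; the CLI wraps it.  Every
run writes a manifest (config hash, seed, package version) so a rerun
with the same manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coupling import DEFAULT_EPSILON, compute_ratio, summarize_rois
from .images import (
    GROUPS,
    VolumeMap,
    load_bold,
    load_cohort_table,
    load_labels,
    load_mask,
    load_motion,
    load_volume,
    save_volume,
)
from .inference import (
    bonferroni_threshold,
    build_design,
    cluster_fwe,
    pearson_with_p,
    posthoc_pairwise,
    voxelwise_ancova,
)
from .perfusion import prepare_cbf
from .preproc import preprocess
from .regression import fit_both, residualize
from .reho import reho_pipeline
from .synthetic import Cohort, CohortSpec, REGION_NAMES, SubjectData, simulate_cohort

CLINICAL_MEASURES = ("duration_months", "MD", "MS", "LV", "RNFL")


@dataclass
class RunConfig:
    """Run settings; the defaults are the analysis' reference settings
    (10 discarded volumes, FD > 0.5 mm spikes, 0.01-0.10 Hz band, 6 mm
    FWHM, cluster-forming p < 1e-3, FWE alpha 0.05)."""

    synthetic: CohortSpec | None = None
    input_dir: str | None = None
    out_dir: str | None = None
    n_discard: int = 10
    fd_threshold_mm: float = 0.5
    head_radius_mm: float = 50.0
    band_hz: tuple[float, float] = (0.01, 0.10)
    fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    cluster_forming_p: float = 1e-3
    fwe_alpha: float = 0.05
    n_perm: int = 500
    epsilon: float = DEFAULT_EPSILON
    connectivity: int = 26
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn is not None:
            if "n_per_group" in syn:
                syn["n_per_group"] = dict(syn["n_per_group"])
            for key in ("grid_shape", "voxel_size_mm", "duration_model"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = CohortSpec(**syn)
        return cfg


def load_cohort(input_dir: str | Path, tr_s: float | None = None) -> Cohort:
    """Load a cohort from the directory layout written by write_cohort."""
    d = Path(input_dir)
    brain = load_mask(d / "brain_mask.nii.gz")
    wm = load_mask(d / "wm_mask.nii.gz")
    csf = load_mask(d / "csf_mask.nii.gz")
    labels = load_labels(d / "region_labels.nii.gz")
    table = load_cohort_table(d / "cohort.tsv")
    subjects = []
    for _, row in table.iterrows():
        sid = str(row["subject"])
        bold = load_bold(
            d / f"{sid}_bold.nii.gz", brain_mask=brain, wm_mask=wm,
            csf_mask=csf, tr_s=tr_s,
        )
        motion = load_motion(d / f"{sid}_motion.txt")
        cbf = load_volume(d / f"{sid}_cbf.nii.gz", mask=brain)
        subjects.append(
            SubjectData(subject=sid, group=str(row["group"]), bold=bold,
                        motion=motion, cbf=cbf)
        )
    from .synthetic import GroundTruth

    truth = GroundTruth(
        region_labels=labels,
        coherence_by_region={},
        cbf_effect_by_region={},
        duration_model=(np.nan, np.nan, np.nan),
        durations=table.set_index("subject")["duration_months"],
        planted_coupling=table.set_index("subject")["duration_months"] * np.nan,
    )
    spec = CohortSpec(
        n_per_group={g: int((table["group"] == g).sum()) for g in GROUPS},
        grid_shape=brain.shape,
        n_timepoints=subjects[0].bold.n_timepoints,
        tr_s=subjects[0].bold.tr_s,
    )
    return Cohort(
        spec=spec, table=table, truth=truth, subjects=subjects,
        brain_mask=brain, wm_mask=wm, csf_mask=csf,
    )


def process_subject(subj: SubjectData, cfg: RunConfig) -> dict[str, VolumeMap]:
    """Per-subject maps: smoothed scaled ReHo, relative CBF, ratio."""
    clean = preprocess(
        subj.bold,
        subj.motion,
        n_discard=cfg.n_discard,
        fd_threshold_mm=cfg.fd_threshold_mm,
        band_hz=cfg.band_hz,
        head_radius_mm=cfg.head_radius_mm,
    )
    reho = reho_pipeline(clean, cfg.fwhm_mm)
    cbf = prepare_cbf(subj.cbf, subj.bold.brain_mask, cfg.fwhm_mm)
    ratio = compute_ratio(reho, cbf, cfg.epsilon)
    return {"reho": reho, "cbf": cbf, "ratio": ratio}


def _common_valid_mask(maps: list[dict[str, VolumeMap]], brain: np.ndarray) -> np.ndarray:
    valid = brain.copy()
    for m in maps:
        valid &= m["ratio"].meta["valid_mask"]
    return valid


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a results dict and (if ``out_dir``)
    writes maps, tables and the run manifest."""
    if cfg.synthetic is None and cfg.input_dir is None:
        cfg = dataclasses.replace(cfg, synthetic=CohortSpec(seed=cfg.seed))
    if cfg.input_dir is not None:
        cohort = load_cohort(cfg.input_dir)
    else:
        cohort = simulate_cohort(cfg.synthetic)

    subject_maps: dict[str, dict[str, VolumeMap]] = {}
    for subj in cohort.subjects:
        try:
            subject_maps[subj.subject] = process_subject(subj, cfg)
        except Exception as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"stage 'subject processing' failed for {subj.subject}"
            ) from exc

    order = [s.subject for s in cohort.subjects]
    valid = _common_valid_mask([subject_maps[s] for s in order], cohort.brain_mask)
    stack = np.stack([subject_maps[s]["ratio"].values[valid] for s in order])
    design = build_design(cohort.table)

    F, p, _ = voxelwise_ancova(stack, design)
    clusters = cluster_fwe(
        stack,
        design,
        valid,
        voxel_size_mm=cohort.spec.voxel_size_mm,
        cluster_forming_p=cfg.cluster_forming_p,
        n_perm=cfg.n_perm,
        seed=np.random.default_rng(cfg.seed),
        connectivity=cfg.connectivity,
        alpha=cfg.fwe_alpha,
    )

    # ROIs: significant clusters when present, otherwise ground-truth regions
    sig_labels = clusters.significant_labels()
    if sig_labels.any():
        roi_labels = sig_labels
        roi_names = {c.label: f"cluster{c.label}" for c in clusters.significant}
        roi_source = "significant_clusters"
    else:
        roi_labels = np.where(cohort.truth.region_labels > 1, cohort.truth.region_labels, 0)
        roi_names = {rid: name for rid, name in REGION_NAMES.items() if rid > 1}
        roi_source = "ground_truth_regions"

    roi_table = summarize_rois(subject_maps, roi_labels, roi_names)
    posthoc = posthoc_pairwise(roi_table, cohort.table)

    # Pearson correlations: ratio vs CBF and ratio vs ReHo per patient group
    corr_alpha = bonferroni_threshold(max(1, roi_table["roi"].nunique()), 2, 2)
    corr_rows = []
    merged = roi_table.merge(cohort.table[["subject", "group"]], on="subject")
    for grp in ("A-LHON", "C-LHON"):
        for roi in sorted(roi_table["roi"].unique()):
            sub = merged[(merged["group"] == grp) & (merged["roi"] == roi)]
            for other in ("cbf", "reho"):
                ok = sub[["ratio", other]].notna().all(axis=1)
                if ok.sum() < 3:
                    continue
                r, pv = pearson_with_p(sub.loc[ok, "ratio"], sub.loc[ok, other])
                corr_rows.append(
                    {
                        "group": grp,
                        "roi": roi,
                        "pair": f"ratio-{other}",
                        "r": r,
                        "p": pv,
                        "significant": pv < corr_alpha,
                        "alpha_family": corr_alpha,
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    regressions = clinical_regressions(roi_table, cohort.table)

    results = {
        "cohort": cohort,
        "subject_maps": subject_maps,
        "valid_mask": valid,
        "design": design,
        "f_values": F,
        "p_values": p,
        "clusters": clusters,
        "roi_source": roi_source,
        "roi_table": roi_table,
        "posthoc": posthoc,
        "correlations": correlations,
        "regressions": regressions,
    }
    if cfg.out_dir is not None:
        _write_outputs(cfg, results)
    return results


def clinical_regressions(
    roi_table: pd.DataFrame,
    cohort: pd.DataFrame,
    measures: tuple[str, ...] = CLINICAL_MEASURES,
) -> pd.DataFrame:
    """Linear + exponential fits of age/gender-residualised ROI coupling
    on each clinical measure, patients only (duration is undefined for
    controls), Bonferroni over nROIs x nMeasures x 2 models."""
    rois = sorted(roi_table["roi"].unique())
    alpha = bonferroni_threshold(len(rois), len(measures), 2)
    merged = roi_table.merge(cohort, on="subject", how="left")
    patients = merged[merged["group"] != "HC"]
    rows = []
    for roi in rois:
        sub = patients[patients["roi"] == roi]
        for measure in measures:
            ok = sub[[measure, "ratio", "age"]].notna().all(axis=1)
            d = sub[ok]
            if len(d) < 6 or np.ptp(d[measure].to_numpy(float)) == 0:
                continue
            gender = (d["gender"].astype(str).str.upper().str.startswith("M")).astype(float)
            covs = np.column_stack([d["age"].to_numpy(float), gender])
            # a constant column (e.g. all-male patient subset) carries no
            # information and would be collinear with the intercept
            covs = covs[:, np.ptp(covs, axis=0) > 0]
            resid = residualize(d["ratio"].to_numpy(float), covs)
            # keep the coupling scale: residual + original mean
            yr = resid + float(d["ratio"].mean())
            fits = fit_both(d[measure].to_numpy(float), yr, alpha_family=alpha)
            for name, f in fits.items():
                rows.append(
                    {
                        "roi": roi,
                        "x": measure,
                        "model": name,
                        **{f"param_{k}": v for k, v in f.params.items()},
                        "adj_r2": f.adj_r2,
                        "p": f.p_value,
                        "n": f.n,
                        "converged": f.converged,
                        "significant": f.significant,
                        "alpha_family": alpha,
                    }
                )
    return pd.DataFrame(rows)


def _write_outputs(cfg: RunConfig, results: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort: Cohort = results["cohort"]
    vx = cohort.spec.voxel_size_mm
    save_volume(results["clusters"].f_map, out / "group_F.nii.gz")
    for name, df in (
        ("clusters", results["clusters"].to_frame()),
        ("roi_summary", results["roi_table"]),
        ("posthoc", results["posthoc"]),
        ("correlations", results["correlations"]),
        ("regressions", results["regressions"]),
    ):
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    # group mean maps
    for kind in ("reho", "cbf", "ratio"):
        for grp in GROUPS:
            subs = [s.subject for s in cohort.subjects if s.group == grp]
            if not subs:
                continue
            mean = np.mean(
                [results["subject_maps"][s][kind].values for s in subs], axis=0
            )
            vol = VolumeMap(values=mean, mask=cohort.brain_mask, voxel_size_mm=vx)
            save_volume(vol, out / f"mean_{kind}_{grp}.nii.gz")
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "roi_source": results["roi_source"],
        "n_significant_clusters": len(results["clusters"].significant),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
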