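"""Group inference: voxel-wise three-group ANCOVA, permutation
cluster-extent FWE, covariate-adjusted post-hoc contrasts, Pearson
correlations, and the demographic tests recomputable from printed
summary statistics.

The voxel-wise model is cell-means coded: three group-mean columns plus
mean-centred age and 0/1 gender; the omnibus F compares it to the
reduced model (one mean + covariates), giving F with (2, N-5) degrees
of freedom.  Cluster-extent family-wise error is controlled by
Freedman-Lane permutation: residuals of the reduced model are permuted
(covariates respected under the null) and the null distribution of the
maximum supra-threshold cluster size is accumulated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import GROUPS, VolumeMap


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignMatrix:
    """Cell-means design (one column per group) + centred age + gender."""

    X_full: np.ndarray
    X_reduced: np.ndarray
    group_index: np.ndarray  # integer group per row
    group_names: tuple[str, ...]
    subjects: list[str]

    @property
    def n(self) -> int:
        return self.X_full.shape[0]

    @property
    def df_effect(self) -> int:
        return len(self.group_names) - 1

    @property
    def df_resid(self) -> int:
        return self.n - self.X_full.shape[1]


def build_design(cohort: pd.DataFrame, groups: tuple[str, ...] = GROUPS) -> DesignMatrix:
    df = cohort.reset_index(drop=True)
    unknown = set(df["group"]) - set(groups)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    gidx = np.array([groups.index(g) for g in df["group"]])
    cells = np.zeros((len(df), len(groups)))
    cells[np.arange(len(df)), gidx] = 1.0
    age = df["age"].to_numpy(float)
    age_c = age - age.mean()
    gender = np.where(df["gender"].astype(str).str.upper().str.startswith("M"), 1.0, 0.0)
    X_full = np.column_stack([cells, age_c, gender])
    X_reduced = np.column_stack([np.ones(len(df)), age_c, gender])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return DesignMatrix(
        X_full=X_full,
        X_reduced=X_reduced,
        group_index=gidx,
        group_names=tuple(groups),
        subjects=list(df["subject"].astype(str)),
    )


def _orthonormal(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _f_stack(Y: np.ndarray, Qf: np.ndarray, Qr: np.ndarray, df1: int, df2: int):
    """F per column of Y for full (Qf) vs reduced (Qr) orthonormal bases."""
    tot = np.einsum("ij,ij->j", Y, Y)
    pf = Qf.T @ Y
    pr = Qr.T @ Y
    rss_f = tot - np.einsum("ij,ij->j", pf, pf)
    rss_r = tot - np.einsum("ij,ij->j", pr, pr)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return F, rss_f


def voxelwise_ancova(stack: np.ndarray, design: DesignMatrix):
    """Voxel-wise omnibus group F (full vs covariates-only model).

    Parameters
    ----------
    stack : ndarray, shape (N subjects, V voxels)

    Returns
    -------
    F : ndarray (V,); zero-variance voxels get F = 0
    p : ndarray (V,); parametric p from F(df_effect, df_resid)
    excluded : bool ndarray (V,) marking zero-variance voxels
    """
    Y = np.asarray(stack, float)
    if Y.shape[0] != design.n:
        raise ValueError("stack rows must match design rows")
    for g in range(len(design.group_names)):
        if (design.group_index == g).sum() < 3:
            raise ValueError("need at least 3 subjects per group")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    excluded = np.einsum("ij,ij->j", Yc, Yc) <= 0
    Qf = _orthonormal(design.X_full)
    Qr = _orthonormal(design.X_reduced)
    df1, df2 = design.df_effect, design.df_resid
    F, _ = _f_stack(Y, Qf, Qr, df1, df2)
    F = np.where(excluded | ~np.isfinite(F), 0.0, np.maximum(F, 0.0))
    p = stats.f.sf(F, df1, df2)
    p[excluded] = 1.0
    return F, p, excluded


# ---------------------------------------------------------------------------
# cluster-extent FWE by Freedman-Lane permutation


@dataclass
class ClusterRecord:
    label: int
    n_voxels: int
    peak_f: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list[ClusterRecord]
    label_volume: np.ndarray
    f_map: VolumeMap
    f_threshold: float
    max_null_sizes: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> list[ClusterRecord]:
        return [c for c in self.clusters if c.p_corrected < self.alpha]

    def significant_labels(self) -> np.ndarray:
        out = np.zeros_like(self.label_volume)
        for c in self.significant:
            out[self.label_volume == c.label] = c.label
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": c.label,
                    "n_voxels": c.n_voxels,
                    "peak_F": c.peak_f,
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                    "p_fwe": c.p_corrected,
                }
                for c in self.clusters
            ]
        )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), bool)
    if connectivity == 18:
        s = np.ones((3, 3, 3), bool)
        for corner in itertools.product((0, 2), repeat=3):
            s[corner] = False
        return s
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def cluster_fwe(
    stack: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    voxel_size_mm=(2.0, 2.0, 2.0),
    cluster_forming_p: float = 1e-3,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    connectivity: int = 26,
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-extent FWE-corrected group inference on a map stack.

    ``stack`` is (N subjects, V voxels) over the in-mask voxels of
    ``mask`` (ravel order).  The voxel-wise F map is thresholded at the
    parametric cluster-forming p; connected components (26-connectivity
    by default) are measured; the null distribution of the maximum
    cluster size comes from Freedman-Lane permutation of reduced-model
    residuals.  Corrected p of each observed cluster is the proportion
    of permutations whose maximum cluster size reaches its size.
    """
    if not (0.0 < cluster_forming_p < 1.0):
        raise ValueError("cluster_forming_p must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    mask = np.asarray(mask, bool)
    Y = np.asarray(stack, float)
    if Y.shape[1] != int(mask.sum()):
        raise ValueError("stack columns must match in-mask voxel count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Qf = _orthonormal(design.X_full)
    Qr = _orthonormal(design.X_reduced)
    df1, df2 = design.df_effect, design.df_resid
    f_crit = stats.f.isf(cluster_forming_p, df1, df2)
    structure = _connectivity_structure(connectivity)

    F_obs, _ = _f_stack(Y, Qf, Qr, df1, df2)
    F_obs = np.where(np.isfinite(F_obs), F_obs, 0.0)
    f_vol = np.zeros(mask.shape)
    f_vol[mask] = F_obs
    supra = f_vol > f_crit
    lab_vol, n_lab = ndimage.label(supra, structure=structure)

    # Freedman-Lane: permute reduced-model residuals, refit the full model
    resid_r = Y - Qr @ (Qr.T @ Y)
    n = design.n
    max_sizes = np.empty(n_perm)
    vol = np.zeros(mask.shape)
    for j in range(n_perm):
        perm = rng.permutation(n)
        Fp, _ = _f_stack(resid_r[perm], Qf, Qr, df1, df2)
        vol[mask] = np.where(np.isfinite(Fp), Fp, 0.0)
        lab_p, n_p = ndimage.label(vol > f_crit, structure=structure)
        if n_p:
            max_sizes[j] = ndimage.sum_labels(
                np.ones_like(lab_p), lab_p, index=np.arange(1, n_p + 1)
            ).max()
        else:
            max_sizes[j] = 0.0

    clusters = []
    vx = np.asarray(voxel_size_mm, float)
    for lab in range(1, n_lab + 1):
        sel = lab_vol == lab
        size = int(sel.sum())
        idx = np.argwhere(sel)
        peak_rel = np.argmax(f_vol[sel])
        peak_ijk = tuple(int(v) for v in idx[peak_rel])
        clusters.append(
            ClusterRecord(
                label=lab,
                n_voxels=size,
                peak_f=float(f_vol[sel].max()),
                peak_ijk=peak_ijk,
                peak_mm=tuple(float(v) for v in np.array(peak_ijk) * vx),
                p_corrected=float(np.mean(max_sizes >= size)),
            )
        )
    clusters.sort(key=lambda c: -c.n_voxels)
    return ClusterResult(
        clusters=clusters,
        label_volume=lab_vol,
        f_map=VolumeMap(values=f_vol, mask=mask, voxel_size_mm=tuple(vx)),
        f_threshold=float(f_crit),
        max_null_sizes=max_sizes,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ROI post-hoc contrasts


def bonferroni_threshold(*family_sizes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / prod(family_sizes)."""
    return alpha / math.prod(family_sizes)


def posthoc_pairwise(
    roi_table: pd.DataFrame,
    cohort: pd.DataFrame,
    measures: tuple[str, ...] = ("ratio", "reho", "cbf"),
    alpha_family: float | None = None,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Covariate-adjusted pairwise group contrasts per ROI x measure.

    Each contrast is the t statistic of the group-mean difference in the
    cell-means ANCOVA (age + gender covariates), with N-5 residual df.
    The Bonferroni family defaults to alpha / (nROIs * nMeasures *
    nPairs).
    """
    rois = sorted(roi_table["roi"].unique())
    pairs = list(itertools.combinations(groups, 2))
    if alpha_family is None:
        alpha_family = bonferroni_threshold(len(rois), len(measures), len(pairs))
    merged = roi_table.merge(cohort, on="subject", how="left")
    rows = []
    for roi in rois:
        sub = merged[merged["roi"] == roi]
        design = build_design(sub, groups)
        X = design.X_full
        XtX_inv = np.linalg.inv(X.T @ X)
        for measure in measures:
            y = sub[measure].to_numpy(float)
            beta = XtX_inv @ (X.T @ y)
            resid = y - X @ beta
            df = design.df_resid
            sigma2 = float(resid @ resid) / df
            for g1, g2 in pairs:
                cvec = np.zeros(X.shape[1])
                cvec[groups.index(g1)] = 1.0
                cvec[groups.index(g2)] = -1.0
                est = float(cvec @ beta)
                se = float(np.sqrt(sigma2 * (cvec @ XtX_inv @ cvec)))
                t = est / se if se > 0 else np.nan
                p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
                rows.append(
                    {
                        "roi": roi,
                        "measure": measure,
                        "group1": g1,
                        "group2": g2,
                        "estimate": est,
                        "t": t,
                        "p": p,
                        "significant": bool(p < alpha_family) if np.isfinite(p) else False,
                        "alpha_family": alpha_family,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scalar statistics


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    n = x.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclass
class GroupSummaryStats:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _coerce_summary(g) -> GroupSummaryStats:
    if isinstance(g, GroupSummaryStats):
        return g
    return GroupSummaryStats(*g)


def oneway_anova_from_summary(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA F from per-group (n, mean, sd) summaries.

    Returns (F, df_between, df_within, p).  Exactly matches raw-data
    ANOVA for any data with these summaries.
    """
    gs = [_coerce_summary(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    N = sum(g.n for g in gs)
    k = len(gs)
    grand = sum(g.n * g.mean for g in gs) / N
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ssw = sum((g.n - 1) * g.sd**2 for g in gs)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return float(F), k - 1, N - k, float(stats.f.sf(F, k - 1, N - k))


def two_sample_t_from_summary(a, b) -> tuple[float, int, float]:
    """Pooled-variance Student t from two (n, mean, sd) summaries."""
    a = _coerce_summary(a)
    b = _coerce_summary(b)
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    obs = np.asarray(table, float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fisher_exact_rxc(table, max_tables: int = 2_000_000) -> float:
    """Exact conditional independence test for a small r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (multivariate hypergeometric null).  Raises if the enumeration
    budget is exceeded — intended for small demographic tables.
    """
    obs = np.asarray(table, int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    N = int(obs.sum())
    lgam = math.lgamma
    const = sum(lgam(r + 1) for r in row) + sum(lgam(c + 1) for c in col) - lgam(N + 1)

    def log_prob(cells) -> float:
        return const - sum(lgam(v + 1) for v in cells)

    lp_obs = log_prob(obs.ravel())
    tol = 1e-9
    r, c = obs.shape
    total = 0.0
    count = 0

    def rec_row(i, col_rem, cells):
        nonlocal total, count
        if i == r - 1:
            last = col_rem
            if np.any(last < 0):
                return
            count += 1
            if count > max_tables:
                raise RuntimeError(
                    "enumeration budget exceeded; fisher_exact_rxc is for small tables"
                )
            lp = log_prob(cells + list(last))
            if lp <= lp_obs + tol:
                total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def rec_cell(j, remaining, col_rem, cells):
            if j == c - 1:
                if remaining <= col_rem[j]:
                    cr = col_rem.copy()
                    cr[j] -= remaining
                    rec_row(i + 1, cr, cells + [remaining])
                return
            for v in range(min(remaining, col_rem[j]) + 1):
                cr = col_rem.copy()
                cr[j] -= v
                rec_cell(j + 1, remaining - v, cr, cells + [v])

        rec_cell(0, int(row[i]), col_rem, cells)

    rec_row(0, col.astype(int).copy(), [])
    return float(min(1.0, total))
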