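"""Coupling-clinical regression: residualise for age/gender, then fit
linear and three-parameter exponential (Y = a*exp(b*x) + c) models.

Adjusted R^2 is 1 - (1 - R^2)(n - 1)/(n - p - 1) with p = 1 for the
linear slope model and p = 3 for the exponential; it may be negative.
The exponential p-value is the extra-sum-of-squares F of the 3-parameter
model against the intercept-only model, since the fit is nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit


def residualize(y, covariates) -> np.ndarray:
    """Least-squares residual of y on [1, covariates] (mean 0).

    ``covariates`` is an (n, k) array — typically age and 0/1 gender.
    """
    y = np.asarray(y, float)
    C = np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != y.size:
        C = C.T
    if C.shape[0] != y.size:
        raise ValueError("covariate rows must match y")
    X = np.column_stack([np.ones(y.size), C])
    if y.size <= X.shape[1]:
        raise ValueError("too few observations to residualise")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class RegressionFit:
    model: str  # 'linear' or 'exponential'
    params: dict  # linear: slope, intercept; exponential: a, b, c
    se: dict
    r2: float
    adj_r2: float
    p_value: float
    n: int
    converged: bool = True
    notes: str = ""
    significant: bool | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.model == "linear":
            return self.params["slope"] * x + self.params["intercept"]
        return self.params["a"] * np.exp(self.params["b"] * x) + self.params["c"]


def _adj_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares Y = slope*x + intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return RegressionFit(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        se={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
        r2=r2,
        adj_r2=_adj_r2(r2, x.size, 1),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def _exp_model(x, a, b, c):
    # exponent clipped to the float range so bad starts fail gracefully
    with np.errstate(over="ignore", invalid="ignore"):
        return a * np.exp(np.clip(b * x, -700.0, 700.0)) + c


def _profile_ac(x, y, b):
    """For fixed b, solve (a, c) by linear least squares; return SSE."""
    e = np.exp(np.clip(b * x, -50, 50))
    X = np.column_stack([e, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(((y - X @ coef) ** 2).sum())
    return coef[0], coef[1], sse


def _b_candidates(x, y):
    """Rate-constant starting points: a log-linear pre-fit on the
    detrended |y - median| plus a sign-symmetric grid scaled to the
    predictor range."""
    cands = []
    z = np.abs(y - np.median(y))
    pos = z > 1e-12
    if pos.sum() >= 3 and np.ptp(x[pos]) > 0:
        slope = stats.linregress(x[pos], np.log(z[pos])).slope
        if np.isfinite(slope) and slope != 0:
            cands.append(float(slope))
    xr = float(np.ptp(x)) or 1.0
    for s in (0.2, 0.05, 0.01):
        cands.extend([s, -s, s * 10.0 / xr, -s * 10.0 / xr])
    return cands


def fit_exponential(x, y) -> RegressionFit:
    """Nonlinear least squares Y = a*exp(b*x) + c with multi-start.

    Each candidate b gets profiled (a, c); the best full refinement by
    SSE wins.  Standard errors come from the curvature of the final
    fit; non-convergence from every start yields a flagged fit rather
    than an exception.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need matched x, y with n >= 5")
    n = x.size
    sst = float(((y - y.mean()) ** 2).sum())

    best = None
    for b0 in _b_candidates(x, y):
        a0, c0, _ = _profile_ac(x, y, b0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    _exp_model, x, y, p0=[a0, b0, c0], maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(((y - _exp_model(x, *popt)) ** 2).sum())
        if not np.isfinite(sse):
            continue
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)

    if best is None:
        return RegressionFit(
            model="exponential",
            params={"a": np.nan, "b": np.nan, "c": np.nan},
            se={"a": np.nan, "b": np.nan, "c": np.nan},
            r2=np.nan,
            adj_r2=np.nan,
            p_value=np.nan,
            n=n,
            converged=False,
            notes="no start converged",
        )
    sse, popt, pcov = best
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    df1, df2 = 2, n - 3  # 3-parameter model vs intercept-only
    if sse > 0 and df2 > 0:
        F = ((sst - sse) / df1) / (sse / df2)
        p = float(stats.f.sf(F, df1, df2))
    else:
        p = 0.0
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return RegressionFit(
        model="exponential",
        params={"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
        se={"a": float(se[0]), "b": float(se[1]), "c": float(se[2])},
        r2=r2,
        adj_r2=_adj_r2(r2, n, 3),
        p_value=p,
        n=n,
    )


def fit_both(x, y, alpha_family: float | None = None) -> dict[str, RegressionFit]:
    """Linear and exponential fits with an optional family threshold."""
    fits = {"linear": fit_linear(x, y), "exponential": fit_exponential(x, y)}
    if alpha_family is not None:
        for f in fits.values():
            f.significant = bool(np.isfinite(f.p_value) and f.p_value < alpha_family)
    return fits
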