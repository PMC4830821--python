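"""Case risk as a function of the abnormal-domain count.

Two complementary fits of the 0/1 case label on the integer count of
abnormal functional domains:

* a single-covariate logistic regression, maximum likelihood via
  iteratively reweighted least squares (IRLS), giving the parametric risk
  curve expit(a + b * count);
* Cleveland-style lowess (tricube-weighted local linear regression with
  optional bisquare robustness iterations), giving a non-parametric curve
  evaluated at each integer count and clipped to [0, 1].

Both are deliberately self-contained: the model is two parameters and the
smoother a few dozen lines, and owning them keeps the score equations and
window arithmetic open to direct testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "LogisticFit",
    "RiskCurve",
    "fit_logistic",
    "predict_risk",
    "lowess_fit",
    "risk_table",
]


@dataclass
class LogisticFit:
    """Maximum-likelihood logit(p) = intercept + slope * count."""

    intercept: float
    slope: float
    converged: bool
    separated: bool
    n_iter: int
    log_likelihood: float


@dataclass
class RiskCurve:
    """Fitted risk over the integer evaluation grid 0..D."""

    method: str  # "logistic" | "lowess"
    grid: np.ndarray
    risk: np.ndarray  # probabilities in [0, 1]
    params: dict


def _check_xy(counts, labels, binary=True):
    x = np.asarray(counts, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("counts and labels must be equal-length vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if binary and not np.isin(y, (0.0, 1.0)).all():
        raise InvalidArgumentError("labels must be binary 0/1")
    return x, y


def fit_logistic(
    counts,
    labels,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """IRLS maximum likelihood for logit(p) = a + b * count.

    Stops when the log-likelihood improves by less than ``tol`` (or after
    ``max_iter`` Newton steps).  Complete separation — a count value that
    splits cases from controls perfectly — has no finite MLE; it is detected
    and reported via ``separated=True`` rather than left to diverge silently.
    """
    x, y = _check_xy(counts, labels)
    if x.size == 0 or y.min() == y.max():
        raise DegenerateInputError("logistic fit needs both classes")
    if x.min() == x.max():
        raise DegenerateInputError("counts are constant; slope is unidentifiable")

    separated = x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        # Newton step via weighted least squares on the working response
        z = eta + (y - p) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 700.0)))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 700.0)))))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        converged=converged,
        separated=bool(separated),
        n_iter=it,
        log_likelihood=ll,
    )


def predict_risk(intercept: float, slope: float, count) -> np.ndarray | float:
    """expit(intercept + slope * count)."""
    if not (np.isfinite(intercept) and np.isfinite(slope)):
        raise InvalidArgumentError("logistic coefficients must be finite")
    out = expit(intercept + slope * np.asarray(count, dtype=float))
    return float(out) if out.ndim == 0 else out


def _local_linear(x0: float, x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted least-squares line through (x, y), evaluated at x0."""
    sw = w.sum()
    if sw == 0.0:  # robustness weights wiped the window; use plain means
        w = np.ones_like(w)
        sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * max(sw, 1.0):
        return ym  # window is effectively one x-value: weighted mean
    b = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym + b * (x0 - xm)


def _tricube_weights(x0: float, x: np.ndarray, frac: float) -> np.ndarray:
    n = x.size
    r = max(2, int(np.ceil(frac * n)))
    d = np.abs(x - x0)
    h = np.sort(d)[min(r, n) - 1]
    if h == 0.0:
        # all nearest neighbours sit at x0 (heavy ties); widen to the nearest
        # strictly positive distance so the local line is identifiable
        pos = d[d > 0]
        if pos.size == 0:
            return (d == 0).astype(float)
        h = pos.min()
        warnings.warn(
            "lowess window contained a single distinct x; widened", stacklevel=3
        )
    u = np.clip(d / h, 0.0, 1.0)
    w = (1.0 - u**3) ** 3
    if w.sum() == 0.0:  # every in-window point sits exactly at distance h
        w = (d <= h).astype(float)
    return w


def lowess_fit(
    counts,
    labels,
    frac: float = 2.0 / 3.0,
    robust_iters: int = 3,
    grid=None,
) -> RiskCurve:
    """Cleveland lowess of the 0/1 labels on the domain count.

    ``frac`` is the fraction of subjects in each local window (tricube
    kernel over neighbour distance, windows over subjects rather than over
    distinct counts); ``robust_iters`` bisquare reweighting passes damp the
    influence of outlying labels.  Evaluated at ``grid`` (default: every
    integer 0..max(count)); output clipped to [0, 1].
    """
    x, y = _check_xy(counts, labels, binary=False)
    if x.size < 5:
        raise DegenerateInputError("lowess needs at least 5 points")
    if not (0.0 < frac <= 1.0):
        raise InvalidArgumentError("bandwidth fraction must lie in (0, 1]")
    if grid is None:
        grid = np.arange(0, int(np.nanmax(x)) + 1)
    grid = np.asarray(grid, dtype=float)

    delta = np.ones_like(x)
    # robustness weights are defined at the data points, so fit there too
    for _ in range(max(0, robust_iters)):
        fitted = np.array(
            [_local_linear(xi, x, y, _tricube_weights(xi, x, frac) * delta) for xi in x]
        )
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s == 0.0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        delta = (1.0 - u**2) ** 2

    risk = np.array(
        [_local_linear(g, x, y, _tricube_weights(g, x, frac) * delta) for g in grid]
    )
    return RiskCurve(
        method="lowess",
        grid=grid.astype(int),
        risk=np.clip(risk, 0.0, 1.0),
        params={"frac": frac, "robust_iters": robust_iters},
    )


def risk_table(counts, labels, frac: float = 2.0 / 3.0, robust_iters: int = 3):
    """Two-row percent-risk table (logistic and lowess) over counts 0..D.

    Returns a pandas DataFrame with one column per integer count, risks in
    percent rounded to 2 decimals.
    """
    import pandas as pd

    fit = fit_logistic(counts, labels)
    x, _ = _check_xy(counts, labels)
    grid = np.arange(0, int(np.nanmax(x)) + 1)
    logistic_pct = 100.0 * predict_risk(fit.intercept, fit.slope, grid)
    low = lowess_fit(counts, labels, frac=frac, robust_iters=robust_iters, grid=grid)
    return pd.DataFrame(
        {
            int(g): [round(float(lp), 2), round(float(np_), 2)]
            for g, lp, np_ in zip(grid, logistic_pct, 100.0 * low.risk)
        },
        index=["% risk (logistic)", "% risk (lowess)"],
    )
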