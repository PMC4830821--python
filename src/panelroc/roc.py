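"""Empirical ROC analysis and diagnostic-performance arithmetic.

This module is the atomic computation the hierarchical cascade reuses at
three levels: continuous biomarker values, integer within-domain abnormality
tallies, and the model-level abnormal-domain count.  A marker is "abnormal"
either above a cutoff (``high_abnormal``) or below it (``low_abnormal``);
everything downstream (AUC, Youden-optimal cutoff, diagnostic odds ratio,
prevalence-adjusted predictive values) is derived from that dichotomy.

Cases are coded 1 and controls 0 throughout.  Missing values are excluded
pairwise: a subject missing a marker simply does not contribute to that
marker's curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import special, stats

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "Direction",
    "ROCCurve",
    "ROCResult",
    "empirical_roc",
    "auc_with_pvalue",
    "select_cutoff",
    "diagnostic_odds_ratio",
    "predictive_values",
    "accuracy_index",
    "spearman_rho",
    "roc_result",
]


class Direction(str, Enum):
    """Which tail of a marker's distribution counts as abnormal."""

    HIGH = "high_abnormal"
    LOW = "low_abnormal"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            # accept the short spellings used in config files
            short = {"high": cls.HIGH, "low": cls.LOW}
            if value in short:
                return short[value]
            raise InvalidArgumentError(f"unknown direction {value!r}") from None


def _clean(values: Sequence[float], labels: Sequence[int]):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape:
        raise InvalidArgumentError("values and labels must have equal length")
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    if not np.isin(y, (0, 1)).all():
        raise InvalidArgumentError("labels must be binary 0/1")
    return v, y.astype(int)


@dataclass
class ROCCurve:
    """Empirical ROC curve of one marker (or tally) against case status.

    ``thresholds`` are candidate cutoffs: midpoints between adjacent distinct
    observed values, flanked by -inf/+inf so the degenerate "call everyone
    abnormal" / "call no one abnormal" operating points are always present.
    ``sens[i]``/``spec[i]`` are the operating characteristics of classifying
    abnormal on the ``direction`` side of ``thresholds[i]`` (strict
    inequality; immaterial at midpoints).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    direction: Direction
    n_cases: int
    n_controls: int
    case_values: np.ndarray = field(repr=False)
    control_values: np.ndarray = field(repr=False)

    @property
    def n_obs(self) -> int:
        return self.n_cases + self.n_controls

    def auc(self) -> float:
        """Area under the curve by the trapezoid rule.

        With every distinct observed value represented as a threshold this
        equals the Mann-Whitney U statistic divided by n1*n2, ties receiving
        half credit.
        """
        fpr = 1.0 - self.spec
        order = np.lexsort((self.sens, fpr))  # ascending fpr, then sens
        return float(np.trapezoid(self.sens[order], fpr[order]))


def empirical_roc(
    values: Sequence[float],
    labels: Sequence[int],
    direction: Direction | str = Direction.HIGH,
) -> ROCCurve:
    """Build the empirical ROC curve of ``values`` against binary ``labels``.

    NaN entries are dropped pairwise.  Raises :class:`DegenerateInputError`
    unless at least one case and one control remain.
    """
    direction = Direction.coerce(direction)
    v, y = _clean(values, labels)
    cases, controls = v[y == 1], v[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateInputError(
            "ROC needs at least one case and one control with observed values"
        )
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    if direction is Direction.HIGH:
        sens = (cases[None, :] > thresholds[:, None]).mean(axis=1)
        spec = (controls[None, :] <= thresholds[:, None]).mean(axis=1)
    else:
        sens = (cases[None, :] < thresholds[:, None]).mean(axis=1)
        spec = (controls[None, :] >= thresholds[:, None]).mean(axis=1)
    return ROCCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        direction=direction,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        case_values=cases,
        control_values=controls,
    )


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc * auc)
        + (n2 - 1) * (q2 - auc * auc)
    ) / (n1 * n2)
    return math.sqrt(max(var, 0.0))


def auc_with_pvalue(curve: ROCCurve) -> tuple[float, float]:
    """AUC plus a two-sided normal test of AUC = 0.5.

    The standard error is Hanley & McNeil's exponential-model approximation
    evaluated at the observed AUC.  Perfect separation gives SE 0 and p 0.
    """
    if curve.n_cases == 0 or curve.n_controls == 0:
        raise DegenerateInputError("p-value needs both classes")
    auc = curve.auc()
    se = _hanley_mcneil_se(auc, curve.n_cases, curve.n_controls)
    if se == 0.0:
        return auc, (1.0 if auc == 0.5 else 0.0)
    z = (auc - 0.5) / se
    p = float(2.0 * special.ndtr(-abs(z)))
    return auc, p


def select_cutoff(
    curve: ROCCurve, criterion: str = "youden"
) -> tuple[float, float, float]:
    """Pick an operating point on ``curve``.

    ``youden`` (default) maximises J = sens + spec - 1; ``closest_topleft``
    minimises the Euclidean distance to the (0, 1) corner.  Ties are broken
    toward higher specificity (then toward the tighter threshold), so the
    choice is deterministic.  The returned cutoff is a midpoint between
    adjacent observed values (or +/-inf at the extremes).
    """
    if criterion == "youden":
        score = curve.sens + curve.spec - 1.0
    elif criterion == "closest_topleft":
        score = -np.hypot(1.0 - curve.sens, 1.0 - curve.spec)
    else:
        raise InvalidArgumentError(f"unknown cutoff criterion {criterion!r}")
    best = score.max()
    tied = np.flatnonzero(score >= best - 1e-12)
    tied = tied[curve.spec[tied] >= curve.spec[tied].max() - 1e-12]
    i = int(tied[-1] if curve.direction is Direction.HIGH else tied[0])
    return float(curve.thresholds[i]), float(curve.sens[i]), float(curve.spec[i])


def diagnostic_odds_ratio(
    sensitivity: float,
    specificity: float,
    counts: tuple[int, int, int, int] | None = None,
    haldane: bool = False,
) -> float:
    """Diagnostic odds ratio [s/(1-s)] * [sp/(1-sp)].

    Boundary sensitivity/specificity (0 or 1) yields 0.0 or ``inf``.  When
    the raw 2x2 counts ``(tp, fn, tn, fp)`` are supplied with
    ``haldane=True``, 0.5 is added to every cell instead (finite even at the
    boundary).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise InvalidArgumentError("sensitivity and specificity must be in [0, 1]")
    if counts is not None and haldane:
        tp, fn, tn, fp = (c + 0.5 for c in counts)
        return float((tp / fn) * (tn / fp))
    if sensitivity == 1.0 or specificity == 1.0:
        return math.inf
    if sensitivity == 0.0 or specificity == 0.0:
        return 0.0
    return (sensitivity / (1.0 - sensitivity)) * (specificity / (1.0 - specificity))


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Prevalence-adjusted PPV and NPV via Bayes' rule.

    PPV = s*pi / [s*pi + (1-sp)(1-pi)];
    NPV = sp*(1-pi) / [(1-s)*pi + sp*(1-pi)].
    """
    if not (0.0 < prevalence < 1.0):
        raise InvalidArgumentError("prevalence must lie strictly in (0, 1)")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise InvalidArgumentError("sensitivity and specificity must be in [0, 1]")
    s, sp, pi = sensitivity, specificity, prevalence
    ppv_den = s * pi + (1.0 - sp) * (1.0 - pi)
    npv_den = (1.0 - s) * pi + sp * (1.0 - pi)
    ppv = s * pi / ppv_den if ppv_den > 0 else 0.0
    npv = sp * (1.0 - pi) / npv_den if npv_den > 0 else 0.0
    return ppv, npv


def accuracy_index(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Fraction of subjects classified correctly."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise InvalidArgumentError("predictions and labels must have equal length")
    if p.size == 0:
        raise DegenerateInputError("accuracy of an empty prediction vector")
    return float((p == y).mean())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a t-approximation p-value.

    Pairs with a missing member are dropped; at least three complete pairs
    are required.  Computed as Pearson correlation on mid-ranks, which is the
    standard tie correction.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 3:
        raise DegenerateInputError("Spearman correlation needs >= 3 complete pairs")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("constant input has no rank correlation")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class ROCResult:
    """One row of a diagnostic-performance report."""

    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    dor: float
    accuracy: float
    n_obs: int
    n_cases: int
    n_controls: int
    direction: Direction
    ppv: float
    npv: float
    prevalence: float

    def to_row(self) -> dict:
        """Report row with the conventional column set."""
        return {
            "No. Obs": self.n_obs,
            "AUC": self.auc,
            "SENS": self.sensitivity,
            "SPEC": self.specificity,
            "PPV": self.ppv,
            "NPV": self.npv,
            "ROC P value": self.p_value,
            "Odds ratio": self.dor,
            "Accuracy": self.accuracy,
        }


def roc_result(
    values: Sequence[float],
    labels: Sequence[int],
    direction: Direction | str = Direction.HIGH,
    criterion: str = "youden",
    prevalence: float = 0.0035,
) -> ROCResult:
    """Full single-marker workup: curve, AUC + p, cutoff, DOR, PPV/NPV, accuracy.

    ``prevalence`` feeds the predictive values; the low default reflects a
    population-screening setting for psychosis-spectrum conditions.
    """
    curve = empirical_roc(values, labels, direction)
    auc, p = auc_with_pvalue(curve)
    cutoff, sens, spec = select_cutoff(curve, criterion)
    v, y = _clean(values, labels)
    if curve.direction is Direction.HIGH:
        pred = (v > cutoff).astype(int)
    else:
        pred = (v < cutoff).astype(int)
    acc = accuracy_index(pred, y)
    ppv, npv = predictive_values(sens, spec, prevalence)
    return ROCResult(
        auc=auc,
        p_value=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        dor=diagnostic_odds_ratio(sens, spec),
        accuracy=acc,
        n_obs=curve.n_obs,
        n_cases=curve.n_cases,
        n_controls=curve.n_controls,
        direction=curve.direction,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
    )
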