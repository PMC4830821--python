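"""Synthetic case-control biomarker cohorts with known ground truth.

The original patient-level data behind the multi-domain psychosis biomarker
panel are not publicly deposited, so every downstream stage of this package
is exercised on cohorts drawn from an equal-variance binormal model: each
marker is Gaussian in controls, and cases are shifted by the effect size
that reproduces a requested area under the ROC curve.  Only AUCs are
published per marker, and under this model an AUC pins down the
standardised mean shift uniquely (d = sqrt(2) * Phi^-1(AUC)), which is why
the generator is calibrated to AUCs alone.

Markers within a functional domain share a single latent factor, giving one
within-domain correlation parameter; domains are mutually independent.
Severity/disability measures (SIR, GAF, CGI, SOFAS, admission rate,
pension flag) are monotone transforms of a subject-level latent
case-intensity score, attenuated by ``severity_loading``.  Missingness is
completely at random at per-variable rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .errors import InvalidArgumentError
from .roc import Direction

__all__ = [
    "VariableSpec",
    "CohortConfig",
    "BiomarkerTable",
    "FUNCTIONAL_MEASURES",
    "auc_to_effect_size",
    "generate_cohort",
]

#: Functional-outcome columns the generator emits (and readers recognise).
FUNCTIONAL_MEASURES = (
    "SIR",
    "GAF",
    "CGI",
    "SOFAS",
    "admission_rate",
    "pension_flag",
)

#: Standardised case shift of the latent case-intensity score.  Symptom
#: intensity separates cases from controls far more sharply than any single
#: biomarker; two control SDs gives that near-complete separation while
#: leaving overlap in the transformed functional scales.
_SEVERITY_SHIFT = 2.0


@dataclass(frozen=True)
class VariableSpec:
    """One biomarker: its domain, abnormal tail, and generative parameters."""

    name: str
    domain: str
    direction: Direction
    control_mean: float = 0.0
    control_sd: float = 1.0
    target_auc: float = 0.75
    missing_rate: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if not (0.5 < self.target_auc < 1.0):
            raise InvalidArgumentError(
                f"{self.name}: target_auc must lie in (0.5, 1), got {self.target_auc}"
            )
        if not (0.0 <= self.missing_rate < 0.5):
            raise InvalidArgumentError(
                f"{self.name}: missing_rate must lie in [0, 0.5), got {self.missing_rate}"
            )
        if self.control_sd <= 0:
            raise InvalidArgumentError(f"{self.name}: control_sd must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    Identical config (including ``seed``) always yields an identical cohort.
    Defaults mirror the study design this package targets: 67 cases and 67
    age/sex-matched controls.
    """

    variables: tuple[VariableSpec, ...]
    n_cases: int = 67
    n_controls: int = 67
    within_domain_correlation: float = 0.3
    severity_loading: float = 0.8
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InvalidArgumentError("n_cases and n_controls must be positive")
        if not (0.0 <= self.within_domain_correlation < 1.0):
            raise InvalidArgumentError("within_domain_correlation must be in [0, 1)")
        if not (0.0 <= self.severity_loading <= 1.0):
            raise InvalidArgumentError("severity_loading must be in [0, 1]")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("variable names must be unique")

    def with_targets(self, target_auc: float) -> "CohortConfig":
        """Copy of the config with every marker's AUC replaced."""
        return replace(
            self,
            variables=tuple(replace(v, target_auc=target_auc) for v in self.variables),
        )


@dataclass
class BiomarkerTable:
    """Subjects x variables, with group labels and an explicit missingness mask.

    ``data`` holds one row per subject: ``subject_id``, ``group``
    (case/control), the marker columns (NaN where missing — never silently
    zero-filled) and any functional-measure columns.
    """

    data: pd.DataFrame
    marker_names: list[str]
    functional_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ("subject_id", "group"):
            if col not in self.data.columns:
                raise InvalidArgumentError(f"table lacks required column {col!r}")
        bad = set(self.data["group"].unique()) - {"case", "control"}
        if bad:
            raise InvalidArgumentError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        """1 for cases, 0 for controls."""
        return (self.data["group"].to_numpy() == "case").astype(int)

    @property
    def values(self) -> pd.DataFrame:
        """Marker matrix (NaN = missing), indexed like ``data``."""
        return self.data[self.marker_names]

    @property
    def functional(self) -> pd.DataFrame:
        return self.data[self.functional_names]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_csv(self, path) -> None:
        """Write ``subject_id,group,<markers>,<functional>``; missing = empty."""
        cols = ["subject_id", "group", *self.marker_names, *self.functional_names]
        self.data[cols].to_csv(path, index=False, float_format="%.6g")


def auc_to_effect_size(target_auc: float) -> float:
    """Standardised case-control mean shift giving ``target_auc``.

    Under equal-variance normal case and control distributions separated by
    d standard deviations, AUC = Phi(d / sqrt(2)); inverting gives
    d = sqrt(2) * Phi^-1(AUC).
    """
    if not (0.5 < target_auc < 1.0):
        raise InvalidArgumentError(f"target_auc must lie in (0.5, 1), got {target_auc}")
    return float(math.sqrt(2.0) * special.ndtri(target_auc))


def generate_cohort(config: CohortConfig) -> BiomarkerTable:
    """Draw one cohort from the binormal latent-factor model.

    Controls are N(control_mean, control_sd^2) per marker.  Cases are shifted
    by ``auc_to_effect_size(target_auc)`` control SDs toward the abnormal
    tail (the shift is negated for ``low_abnormal`` markers, so units stay
    interpretable).  Markers in the same domain share a latent factor with
    loading sqrt(within_domain_correlation); marginal variances are
    unaffected.  Functional measures are monotone transforms of
    ``severity_loading * L + noise`` where L is the latent case-intensity
    score (standard normal in controls, shifted +2 SD in cases).
    """
    rng = np.random.default_rng(config.seed)
    n1, n0 = config.n_cases, config.n_controls
    n = n1 + n0
    case = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])

    domains = list(dict.fromkeys(v.domain for v in config.variables))
    rho = config.within_domain_correlation
    factor = {d: rng.standard_normal(n) for d in domains}

    columns: dict[str, np.ndarray] = {}
    columns["subject_id"] = np.array(
        [f"S{i + 1:03d}" for i in range(n1)] + [f"C{i + 1:03d}" for i in range(n0)]
    )
    columns["group"] = np.where(case == 1, "case", "control")

    for v in config.variables:
        shift = auc_to_effect_size(v.target_auc)
        if v.direction is Direction.LOW:
            shift = -shift
        noise = rng.standard_normal(n)
        z = math.sqrt(rho) * factor[v.domain] + math.sqrt(1.0 - rho) * noise
        x = v.control_mean + v.control_sd * (shift * case + z)
        if v.missing_rate > 0:
            x = np.where(rng.random(n) < v.missing_rate, np.nan, x)
        columns[v.name] = x

    # Latent case-intensity: what severity raters respond to.
    latent = _SEVERITY_SHIFT * case + rng.standard_normal(n)
    lam = config.severity_loading
    resid = math.sqrt(1.0 - lam * lam)

    def attenuated() -> np.ndarray:
        return lam * latent + resid * rng.standard_normal(n)

    columns["SIR"] = np.clip(42.0 + 30.0 * attenuated(), 24.0, 168.0).round(1)
    columns["GAF"] = np.clip(80.0 - 15.0 * attenuated(), 1.0, 100.0).round(1)
    columns["CGI"] = np.clip(np.rint(2.0 + 1.2 * attenuated()), 1, 7).astype(int)
    columns["SOFAS"] = np.clip(80.0 - 15.0 * attenuated(), 1.0, 100.0).round(1)
    columns["admission_rate"] = rng.poisson(np.exp(-1.0 + 0.7 * attenuated()))
    columns["pension_flag"] = (attenuated() > 1.2).astype(int)

    data = pd.DataFrame(columns)
    return BiomarkerTable(
        data=data,
        marker_names=[v.name for v in config.variables],
        functional_names=list(FUNCTIONAL_MEASURES),
    )
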