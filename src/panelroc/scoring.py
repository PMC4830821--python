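"""The hierarchical dichotomize-tally-re-ROC cascade.

The screening rule is built in three stacked ROC passes:

1. every continuous marker gets its own ROC-optimal cutoff and is scored
   0/1 for abnormality toward its abnormal tail;
2. abnormality flags are tallied within each functional domain, the integer
   tally is itself ROC-analysed, and the Youden-optimal minimum count
   becomes that domain's abnormality threshold;
3. the number of abnormal domains is tallied per subject and ROC-analysed
   once more, yielding the model-level case-detection threshold
   ("call a subject a case at >= T abnormal domains").

Every threshold is an integer, and classification is monotone: making any
marker more abnormal can only move a subject toward the case label.

Missing data policy: cutoffs and tallies use pairwise deletion.  A missing
marker yields a missing flag (never a silent 0); a domain's tally is the sum
of its observed flags provided at least one member is observed; the
model-level ROC is fitted on subjects with all domains observed.  Run the
cascade on an imputed table to avoid any exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateInputError
from .roc import (
    Direction,
    ROCResult,
    accuracy_index,
    auc_with_pvalue,
    diagnostic_odds_ratio,
    empirical_roc,
    predictive_values,
    roc_result,
)

__all__ = [
    "DomainMap",
    "ScoredPanel",
    "PanelModel",
    "dichotomize",
    "tally_domains",
    "fit_domain_thresholds",
    "fit_panel_model",
    "classify",
]


@dataclass(frozen=True)
class DomainMap:
    """Ordered functional domains and the variable -> domain assignment."""

    domains: tuple[str, ...]
    assignment: Mapping[str, str]
    directions: Mapping[str, Direction]

    @classmethod
    def from_assignment(
        cls,
        assignment: Mapping[str, str],
        directions: Mapping[str, Direction | str],
        domain_order: Sequence[str] | None = None,
    ) -> "DomainMap":
        domains = tuple(domain_order) if domain_order else tuple(
            dict.fromkeys(assignment.values())
        )
        missing = set(assignment.values()) - set(domains)
        if missing:
            raise ConfigurationError(f"domains not in order list: {sorted(missing)}")
        undirected = set(assignment) - set(directions)
        if undirected:
            raise ConfigurationError(f"variables lack a direction: {sorted(undirected)}")
        return cls(
            domains=domains,
            assignment=dict(assignment),
            directions={k: Direction.coerce(v) for k, v in directions.items()},
        )

    @property
    def variables(self) -> list[str]:
        return list(self.assignment)

    def members(self, domain: str) -> list[str]:
        return [v for v, d in self.assignment.items() if d == domain]


@dataclass
class ScoredPanel:
    """Per-subject output of the cascade on one table."""

    flags: pd.DataFrame  # 0/1/NaN per variable
    domain_tallies: pd.DataFrame  # integer count of abnormal variables (NaN if domain unobserved)
    domain_abnormal: pd.DataFrame  # 0/1/NaN per domain
    domain_count: pd.Series  # number of abnormal domains
    predicted: pd.Series  # "case"/"control"


@dataclass
class PanelModel:
    """A fitted hierarchical screening rule plus its training performance."""

    cutoffs: dict[str, float]
    directions: dict[str, Direction]
    domain_map: DomainMap
    domain_thresholds: dict[str, int]
    model_threshold: int
    variable_results: dict[str, ROCResult] = field(default_factory=dict)
    domain_results: dict[str, ROCResult] = field(default_factory=dict)
    model_result: ROCResult | None = None
    prevalence: float = 0.0035

    def to_yaml(self, path=None) -> str:
        doc = {
            "schema_version": 1,
            "model_threshold": int(self.model_threshold),
            "variables": {
                name: {
                    "domain": self.domain_map.assignment[name],
                    "direction": self.directions[name].value,
                    "cutoff": float(self.cutoffs[name]),
                }
                for name in self.domain_map.variables
            },
            "domain_order": list(self.domain_map.domains),
            "domain_thresholds": {
                d: int(k) for d, k in self.domain_thresholds.items()
            },
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PanelModel":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        variables = doc["variables"]
        dmap = DomainMap.from_assignment(
            {n: v["domain"] for n, v in variables.items()},
            directions={n: v["direction"] for n, v in variables.items()},
            domain_order=doc.get("domain_order"),
        )
        return cls(
            cutoffs={n: float(v["cutoff"]) for n, v in variables.items()},
            directions={n: Direction.coerce(v["direction"]) for n, v in variables.items()},
            domain_map=dmap,
            domain_thresholds={d: int(k) for d, k in doc["domain_thresholds"].items()},
            model_threshold=int(doc["model_threshold"]),
        )


def dichotomize(
    values: pd.DataFrame,
    cutoffs: Mapping[str, float],
    directions: Mapping[str, Direction | str],
) -> pd.DataFrame:
    """Score each marker 0/1 for abnormality at its cutoff.

    ``high_abnormal``: 1 iff value > cutoff; ``low_abnormal``: 1 iff
    value < cutoff.  Missing values stay NaN.
    """
    flags = {}
    for name in values.columns:
        if name not in cutoffs or name not in directions:
            raise ConfigurationError(f"no cutoff/direction configured for {name!r}")
        v = values[name].to_numpy(dtype=float)
        d = Direction.coerce(directions[name])
        flag = (v > cutoffs[name]) if d is Direction.HIGH else (v < cutoffs[name])
        flags[name] = np.where(np.isnan(v), np.nan, flag.astype(float))
    return pd.DataFrame(flags, index=values.index)


def tally_domains(flags: pd.DataFrame, domain_map: DomainMap) -> pd.DataFrame:
    """Sum abnormality flags per domain; NaN where no member is observed."""
    tallies = {}
    for domain in domain_map.domains:
        members = [m for m in domain_map.members(domain) if m in flags.columns]
        if not members:
            raise ConfigurationError(f"domain {domain!r} has no variables in the table")
        sub = flags[members]
        tally = sub.sum(axis=1, skipna=True)
        tally[sub.isna().all(axis=1)] = np.nan
        tallies[domain] = tally
    return pd.DataFrame(tallies, index=flags.index)


def _best_integer_threshold(
    tally: np.ndarray, labels: np.ndarray, max_count: int, tie: str = "smallest"
) -> int:
    """Youden-optimal minimum count for "abnormal iff tally >= k".

    Ties favour the smallest k by default (a screening rule prefers
    sensitivity); ``tie="largest"`` favours specificity.
    """
    obs = ~np.isnan(tally)
    t, y = tally[obs], labels[obs]
    if t.size == 0:
        raise DegenerateInputError("all tallies missing")
    best_k, best_j = 1, -np.inf
    ks = range(1, max_count + 1) if tie == "smallest" else range(max_count, 0, -1)
    for k in ks:
        pred = t >= k
        sens = pred[y == 1].mean() if (y == 1).any() else np.nan
        spec = (~pred[y == 0]).mean() if (y == 0).any() else np.nan
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_k = j, k
    return best_k


def _tally_roc_result(
    tally: np.ndarray, labels: np.ndarray, k: int, prevalence: float
) -> ROCResult:
    """Diagnostic workup of an integer tally at the fixed threshold k."""
    obs = ~np.isnan(tally)
    t, y = tally[obs], labels[obs]
    curve = empirical_roc(t, y, Direction.HIGH)
    auc, p = auc_with_pvalue(curve)
    pred = (t >= k).astype(int)
    sens = pred[y == 1].mean()
    spec = 1.0 - pred[y == 0].mean()
    ppv, npv = predictive_values(sens, spec, prevalence)
    return ROCResult(
        auc=auc,
        p_value=p,
        cutoff=k - 0.5,  # midpoint form of "count >= k"
        sensitivity=float(sens),
        specificity=float(spec),
        dor=diagnostic_odds_ratio(float(sens), float(spec)),
        accuracy=accuracy_index(pred, y),
        n_obs=curve.n_obs,
        n_cases=curve.n_cases,
        n_controls=curve.n_controls,
        direction=Direction.HIGH,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
    )


def fit_domain_thresholds(
    flags: pd.DataFrame,
    labels: np.ndarray,
    domain_map: DomainMap,
    tie: str = "smallest",
    prevalence: float = 0.0035,
) -> tuple[dict[str, int], dict[str, ROCResult]]:
    """Second ROC pass: per-domain minimum abnormal-variable counts.

    A single-variable domain necessarily reduces to that variable's own
    flag (threshold 1).
    """
    tallies = tally_domains(flags, domain_map)
    labels = np.asarray(labels)
    thresholds: dict[str, int] = {}
    results: dict[str, ROCResult] = {}
    for domain in domain_map.domains:
        tally = tallies[domain].to_numpy(dtype=float)
        size = len(domain_map.members(domain))
        k = 1 if size == 1 else _best_integer_threshold(tally, labels, size, tie)
        thresholds[domain] = k
        results[domain] = _tally_roc_result(tally, labels, k, prevalence)
    return thresholds, results


def fit_panel_model(
    values: pd.DataFrame,
    labels: Sequence[int],
    domain_map: DomainMap,
    cutoff_criterion: str = "youden",
    tie: str = "smallest",
    prevalence: float = 0.0035,
) -> PanelModel:
    """Run the full three-level cascade on a training table.

    ``values`` is the marker matrix (NaN = missing) and ``labels`` the 0/1
    case status.  Raises :class:`DegenerateInputError` (with level context)
    if any level lacks both classes.
    """
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise DegenerateInputError("training data needs both cases and controls")

    cutoffs: dict[str, float] = {}
    var_results: dict[str, ROCResult] = {}
    for name in domain_map.variables:
        if name not in values.columns:
            raise ConfigurationError(f"table lacks panel variable {name!r}")
        try:
            res = roc_result(
                values[name],
                labels,
                domain_map.directions[name],
                criterion=cutoff_criterion,
                prevalence=prevalence,
            )
        except DegenerateInputError as err:
            raise DegenerateInputError(f"variable {name!r}: {err}") from err
        cutoffs[name] = res.cutoff
        var_results[name] = res

    flags = dichotomize(values[domain_map.variables], cutoffs, domain_map.directions)
    try:
        thresholds, dom_results = fit_domain_thresholds(
            flags, labels, domain_map, tie=tie, prevalence=prevalence
        )
    except DegenerateInputError as err:
        raise DegenerateInputError(f"domain level: {err}") from err
    for domain in domain_map.domains:
        members = domain_map.members(domain)
        if len(members) == 1:
            # a tally over one marker is that marker's flag; re-ROC-ing the
            # flag would discard the continuous resolution, so the domain
            # inherits the marker's full ROC workup (threshold stays 1)
            dom_results[domain] = var_results[members[0]]

    tallies = tally_domains(flags, domain_map)
    abnormal = pd.DataFrame(
        {d: (tallies[d] >= thresholds[d]).where(tallies[d].notna()) for d in domain_map.domains}
    )
    complete = abnormal.notna().all(axis=1).to_numpy()
    count = abnormal.sum(axis=1, skipna=True).to_numpy(dtype=float)
    count_fit = np.where(complete, count, np.nan)
    try:
        model_threshold = _best_integer_threshold(
            count_fit, labels, len(domain_map.domains), tie
        )
        model_result = _tally_roc_result(count_fit, labels, model_threshold, prevalence)
    except DegenerateInputError as err:
        raise DegenerateInputError(f"model level: {err}") from err
    if len(domain_map.domains) == 1:
        # degenerate cascade: one domain, so the model level inherits it
        model_result = dom_results[domain_map.domains[0]]

    return PanelModel(
        cutoffs=cutoffs,
        directions=dict(domain_map.directions),
        domain_map=domain_map,
        domain_thresholds=thresholds,
        model_threshold=model_threshold,
        variable_results=var_results,
        domain_results=dom_results,
        model_result=model_result,
        prevalence=prevalence,
    )


def classify(model: PanelModel, values: pd.DataFrame) -> ScoredPanel:
    """Apply a fitted rule to (new) subjects.

    Domain tallies use whichever panel markers are observed; a subject is
    labelled ``case`` iff their abnormal-domain count reaches the model
    threshold.
    """
    cols = [v for v in model.domain_map.variables if v in values.columns]
    missing = set(model.domain_map.variables) - set(cols)
    if missing:
        raise ConfigurationError(f"table lacks panel variables: {sorted(missing)}")
    flags = dichotomize(values[cols], model.cutoffs, model.directions)
    tallies = tally_domains(flags, model.domain_map)
    abnormal = pd.DataFrame(
        {
            d: (tallies[d] >= model.domain_thresholds[d]).where(tallies[d].notna())
            for d in model.domain_map.domains
        }
    )
    count = abnormal.sum(axis=1, skipna=True)
    predicted = pd.Series(
        np.where(count >= model.model_threshold, "case", "control"),
        index=values.index,
    )
    return ScoredPanel(
        flags=flags,
        domain_tallies=tallies,
        domain_abnormal=abnormal,
        domain_count=count,
        predicted=predicted,
    )
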