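"""Model validation: stratified k-fold CV, imputation, functional correlates.

Cross-validation refits the entire cascade — marker cutoffs, domain
thresholds and the model-level threshold — inside every training fold, so
no held-out subject influences any threshold used to score it.  (A
``refit_cutoffs=False`` mode reuses full-data marker cutoffs and refits only
the tally thresholds per fold; it exists to probe how much of the optimism
lives at the cutoff level, and fold metrics from it are labelled as such.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import BiomarkerTable
from .errors import ConfigurationError, DegenerateInputError, InvalidArgumentError
from .roc import (
    Direction,
    auc_with_pvalue,
    diagnostic_odds_ratio,
    empirical_roc,
    predictive_values,
    spearman_rho,
)
from .scoring import DomainMap, classify, fit_panel_model, tally_domains

__all__ = [
    "CVResult",
    "ImputationReport",
    "stratified_kfold",
    "cross_validate",
    "impute_missing",
    "functional_correlates",
]

log = logging.getLogger(__name__)


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Class-stratified random partition into k near-equal folds.

    Cases and controls are shuffled separately and dealt into folds, so
    every fold keeps the cohort's class balance to within one subject.
    Returns an integer fold id (0..k-1) per subject; deterministic in
    ``seed``.
    """
    y = np.asarray(labels)
    if k < 2:
        raise InvalidArgumentError("k must be at least 2")
    rng = np.random.default_rng(seed)
    fold = np.full(y.shape[0], -1, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise InvalidArgumentError(
                f"class {cls} has {idx.size} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        for j, chunk in enumerate(np.array_split(idx, k)):
            fold[chunk] = j
    return fold


@dataclass
class CVResult:
    """Per-fold and pooled diagnostic performance of the cascade."""

    folds: pd.DataFrame  # one row per (fold, prevalence)
    pooled: pd.DataFrame  # concatenated-test-prediction metrics per prevalence
    mean_of_folds: pd.DataFrame  # simple average of fold metrics per prevalence
    fold_assignment: np.ndarray
    counts: pd.Series  # held-out abnormal-domain count per subject
    predictions: pd.Series  # held-out predicted label per subject
    models: dict = field(default_factory=dict)  # fold id -> fitted PanelModel


def _fold_metrics(pred: np.ndarray, count: np.ndarray, y: np.ndarray, prevalences):
    sens = pred[y == 1].mean()
    spec = 1.0 - pred[y == 0].mean()
    try:
        auc, _ = auc_with_pvalue(empirical_roc(count, y, Direction.HIGH))
    except DegenerateInputError:
        auc = np.nan
    rows = []
    for pi in prevalences:
        ppv, npv = predictive_values(float(sens), float(spec), pi)
        rows.append(
            {
                "n_obs": int(y.size),
                "prevalence": pi,
                "sensitivity_pct": 100.0 * sens,
                "specificity_pct": 100.0 * spec,
                "roc_area": auc,
                "odds_ratio": diagnostic_odds_ratio(float(sens), float(spec)),
                "ppv_pct": 100.0 * ppv,
                "npv_pct": 100.0 * npv,
            }
        )
    return rows


def cross_validate(
    table: BiomarkerTable,
    domain_map: DomainMap,
    k: int = 5,
    seed: int = 0,
    prevalences: Sequence[float] = (0.0035, 0.30),
    refit_cutoffs: bool = True,
    **fit_options,
) -> CVResult:
    """Stratified k-fold cross-validation of the full cascade.

    Each fold's model is fitted on the other k-1 folds and applied to the
    held-out fifth; sensitivity/specificity/AUC/DOR are measured on the
    held-out subjects and PPV/NPV recomputed at each requested prevalence.
    The pooled summary scores the concatenated held-out predictions; the
    mean-of-folds summary averages the per-fold metrics.  A training fold
    that degenerates (e.g. a single-class domain) is skipped with a warning.
    """
    y = table.labels
    fold = stratified_kfold(y, k, seed)
    values = table.values

    full_model = None
    if not refit_cutoffs:
        full_model = fit_panel_model(values, y, domain_map, **fit_options)

    fold_rows = []
    models: dict = {}
    pooled_pred = np.full(len(y), np.nan)
    pooled_count = np.full(len(y), np.nan)
    for j in range(k):
        train, test = fold != j, fold == j
        try:
            if refit_cutoffs:
                model = fit_panel_model(values[train], y[train], domain_map, **fit_options)
            else:
                model = _refit_tally_thresholds(
                    values[train], y[train], domain_map, full_model, **fit_options
                )
        except DegenerateInputError as err:
            log.warning("skipping fold %d: %s", j, err)
            continue
        models[j] = model
        scored = classify(model, values[test])
        pred = (scored.predicted.to_numpy() == "case").astype(int)
        count = scored.domain_count.to_numpy(dtype=float)
        pooled_pred[test] = pred
        pooled_count[test] = count
        for row in _fold_metrics(pred, count, y[test], prevalences):
            fold_rows.append({"fold": j + 1, **row})

    if not fold_rows:
        raise DegenerateInputError("every cross-validation fold degenerated")

    folds = pd.DataFrame(fold_rows)
    done = ~np.isnan(pooled_pred)
    pooled = pd.DataFrame(
        _fold_metrics(pooled_pred[done], pooled_count[done], y[done], prevalences)
    )
    mean_of_folds = (
        folds.drop(columns="fold").groupby("prevalence", as_index=False).mean()
    )
    return CVResult(
        folds=folds,
        pooled=pooled,
        mean_of_folds=mean_of_folds,
        fold_assignment=fold,
        counts=pd.Series(pooled_count, index=table.data.index),
        predictions=pd.Series(
            np.where(np.isnan(pooled_pred), None, np.where(pooled_pred == 1, "case", "control")),
            index=table.data.index,
        ),
        models=models,
    )


def _refit_tally_thresholds(values, y, domain_map, full_model, tie="smallest", **_):
    """Training-fold model that reuses full-data marker cutoffs.

    Only the domain and model-level tally thresholds are refitted; used by
    ``cross_validate(refit_cutoffs=False)`` to isolate cutoff-level optimism.
    """
    from .scoring import (
        PanelModel,
        _best_integer_threshold,
        dichotomize,
    )

    flags = dichotomize(
        values[domain_map.variables], full_model.cutoffs, domain_map.directions
    )
    from .scoring import fit_domain_thresholds

    thresholds, dom_results = fit_domain_thresholds(flags, y, domain_map, tie=tie)
    tallies = tally_domains(flags, domain_map)
    abnormal = pd.DataFrame(
        {d: (tallies[d] >= thresholds[d]).where(tallies[d].notna()) for d in domain_map.domains}
    )
    complete = abnormal.notna().all(axis=1).to_numpy()
    count = abnormal.sum(axis=1, skipna=True).to_numpy(dtype=float)
    count_fit = np.where(complete, count, np.nan)
    model_threshold = _best_integer_threshold(count_fit, y, len(domain_map.domains), tie)
    return PanelModel(
        cutoffs=dict(full_model.cutoffs),
        directions=dict(domain_map.directions),
        domain_map=domain_map,
        domain_thresholds=thresholds,
        model_threshold=model_threshold,
        domain_results=dom_results,
    )


@dataclass
class ImputationReport:
    """What was filled in, and how."""

    method: str
    missing_counts: pd.Series
    fill_values: dict = field(default_factory=dict)


def impute_missing(
    table: BiomarkerTable, method: str = "median"
) -> tuple[BiomarkerTable, ImputationReport]:
    """Fill missing marker values; observed values are never altered.

    Methods: ``median`` (default) — overall per-variable median, blind to
    case status so no label information leaks into the features;
    ``group_median`` — per-group median, a label-aware convention some
    clinical pipelines use (leaks labels; for sensitivity probes only);
    ``none`` — leave NaNs for complete-case handling downstream.
    """
    missing = table.values.isna().sum()
    if method == "none":
        return table, ImputationReport("none", missing)
    if method not in ("median", "group_median"):
        raise InvalidArgumentError(f"unknown imputation method {method!r}")

    fully_missing = [c for c in table.marker_names if table.data[c].isna().all()]
    if fully_missing:
        raise ConfigurationError(
            f"cannot impute variables with no observed values: {fully_missing}"
        )
    data = table.data.copy()
    fills: dict = {}
    if method == "median":
        for c in table.marker_names:
            fills[c] = float(data[c].median())
            data[c] = data[c].fillna(fills[c])
    else:
        for c in table.marker_names:
            med = data.groupby("group")[c].transform("median")
            fills[c] = {
                g: float(m) for g, m in data.groupby("group")[c].median().items()
            }
            data[c] = data[c].fillna(med)
    out = BiomarkerTable(
        data=data,
        marker_names=list(table.marker_names),
        functional_names=list(table.functional_names),
    )
    return out, ImputationReport(method, missing, fills)


def functional_correlates(
    scores: pd.DataFrame, measures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (and p) of each score column against each measure column.

    ``scores`` are model/domain abnormality tallies (or the abnormal-domain
    count); ``measures`` are external severity/disability ratings.  Cells
    with fewer than 3 complete pairs are NaN.
    """
    rho = pd.DataFrame(index=scores.columns, columns=measures.columns, dtype=float)
    pval = rho.copy()
    for s in scores.columns:
        for m in measures.columns:
            try:
                r, p = spearman_rho(scores[s], measures[m])
            except DegenerateInputError:
                r, p = np.nan, np.nan
            rho.loc[s, m] = r
            pval.loc[s, m] = p
    return rho, pval


def score_table(table: BiomarkerTable, model) -> pd.DataFrame:
    """Domain tallies, abnormal-domain count and case flag for correlation use."""
    scored = classify(model, table.values)
    out = scored.domain_tallies.copy()
    out["abnormal_domain_count"] = scored.domain_count
    out["case"] = table.labels
    return out
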