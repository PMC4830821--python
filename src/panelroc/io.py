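"""Reading/writing cohorts, run configuration, and report files.

Cohorts travel as plain CSV — one row per subject, ``subject_id`` and
``group`` (case/control) first, marker columns next, any declared
functional-measure columns last, missing values as empty fields.  Panel and
run configuration travel as YAML.  Reports are CSV tables mirroring the
conventional diagnostic-performance layout (No. Obs, AUC, SENS, SPEC, PPV,
NPV, ROC P value, Odds ratio, Accuracy).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import FUNCTIONAL_MEASURES, BiomarkerTable, CohortConfig, VariableSpec
from .errors import InvalidArgumentError
from .scoring import PanelModel

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_panel_config",
    "write_report",
    "result_frame",
]

REPORT_COLUMNS = [
    "No. Obs",
    "AUC",
    "SENS",
    "SPEC",
    "PPV",
    "NPV",
    "ROC P value",
    "Odds ratio",
    "Accuracy",
]


def read_cohort(path, functional_cols=None) -> BiomarkerTable:
    """Parse a cohort CSV into a typed table with an explicit missingness mask.

    Columns other than ``subject_id``/``group`` are markers unless named in
    ``functional_cols`` (default: the standard severity/disability measure
    names).  Non-numeric marker cells and unknown group labels raise parse
    errors naming the offending row and column.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise InvalidArgumentError(f"{path}: missing required column {col!r}")
    bad = df.loc[~df["group"].isin(["case", "control"])]
    if len(bad):
        raise InvalidArgumentError(
            f"{path}: unknown group label {bad['group'].iloc[0]!r} at row {bad.index[0]}"
        )
    if functional_cols is None:
        functional_cols = [c for c in FUNCTIONAL_MEASURES if c in df.columns]
    markers = [
        c for c in df.columns if c not in ("subject_id", "group", *functional_cols)
    ]
    for c in markers:
        coerced = pd.to_numeric(df[c], errors="coerce")
        invalid = df[c].notna() & coerced.isna()
        if invalid.any():
            row = int(np.flatnonzero(invalid)[0])
            raise InvalidArgumentError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column {c!r}, row {row}"
            )
        df[c] = coerced
    return BiomarkerTable(
        data=df, marker_names=markers, functional_names=list(functional_cols)
    )


def write_cohort(table: BiomarkerTable, path) -> None:
    table.to_csv(path)


def read_panel_config(path) -> CohortConfig:
    """Load a simulation/panel recipe from YAML (keys mirror CohortConfig)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    variables = tuple(VariableSpec(**v) for v in doc["variables"])
    kwargs = {k: doc[k] for k in (
        "n_cases", "n_controls", "within_domain_correlation", "severity_loading", "seed"
    ) if k in doc}
    return CohortConfig(variables=variables, **kwargs)


def result_frame(results: dict, extra: dict | None = None) -> pd.DataFrame:
    """Stack named ROCResults into a report table with the standard columns."""
    rows = {}
    for name, res in results.items():
        rows[name] = res.to_row()
    df = pd.DataFrame.from_dict(rows, orient="index")[REPORT_COLUMNS]
    if extra:
        for col, mapping in extra.items():
            df.insert(0, col, pd.Series(mapping))
    df.index.name = "name"
    return df


def _config_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_report(
    outdir,
    model: PanelModel,
    cv=None,
    risk: pd.DataFrame | None = None,
    correlates: pd.DataFrame | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the fitted-model report files under ``outdir``.

    Emits variable-, domain- and model-level performance tables, the fitted
    thresholds (YAML), optional risk/CV/correlation tables, and a run log
    recording seed, config hash and package version so the run is
    reproducible from its artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame):
        p = outdir / name
        df.to_csv(p, float_format="%.6g")
        written[name] = p

    emit(
        "variables.csv",
        result_frame(
            model.variable_results,
            extra={
                "cutoff": model.cutoffs,
                "domain": dict(model.domain_map.assignment),
            },
        ),
    )
    emit(
        "domains.csv",
        result_frame(
            model.domain_results,
            extra={
                "n_variables": {d: len(model.domain_map.members(d)) for d in model.domain_map.domains},
                "threshold": model.domain_thresholds,
            },
        ),
    )
    if model.model_result is not None:
        emit(
            "model.csv",
            result_frame(
                {"panel": model.model_result},
                extra={"threshold_domains": {"panel": model.model_threshold}},
            ),
        )
    model.to_yaml(outdir / "model.yaml")
    written["model.yaml"] = outdir / "model.yaml"

    if risk is not None:
        emit("risk.csv", risk)
    if cv is not None:
        emit("crossval_folds.csv", cv.folds.set_index("fold"))
        emit("crossval_pooled.csv", cv.pooled.set_index("prevalence"))
    if correlates is not None:
        emit("correlates.csv", correlates)

    run_log = {
        "panelroc_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
        "files": sorted(written),
    }
    log_path = outdir / "run.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    written["run.json"] = log_path
    return written
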