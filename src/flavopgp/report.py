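"""End-to-end runs: reproduction on the bundled tables, simulation, prediction.

``run_reproduce`` chains every stage — reversal folds, training-set
correlation matrix, collinearity screen, QSAR fit, internal/external
validation and the per-compound prediction table — and writes one
machine-readable artifact per stage plus a human-readable summary.  Every
number in the summary is traceable to a field in one of the artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as d
from .errors import DomainError, ParseError
from .qsar import QSARModel, fit_ols, fit_pls, format_equation, predict
from .reversal import reversal_table
from .selection import collinearity_filter, pearson_matrix
from .synthetic import SyntheticSpec, gen_descriptor_matrix, gen_response
from .validation import residual_table, validate_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_reproduce", "run_simulate", "run_predict"]

#: concordance bound for |predicted − originally reported prediction| (μM)
CONCORDANCE_TOL = 0.01


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    With all paths ``None`` the packaged study tables are used.  Thresholds
    follow the pipeline defaults: entry/removal p-values 0.05/0.10, pairwise
    collinearity bound 0.5, full-rank fit.
    """

    descriptors_path: str | None = None
    cytotoxicity_path: str | None = None
    test_ids: frozenset[int] | None = None  # None -> default split
    p_enter: float = 0.05
    p_remove: float = 0.10
    collinearity_threshold: float = 0.5
    method: str = "ols"  # "ols" | "pls"
    n_components: int | None = None  # pls only; None -> full rank
    out_dir: str = "flavopgp_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_enter", "p_remove", "collinearity_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DomainError(f"{name} must be in (0,1), got {v}")
        if self.method not in ("ols", "pls"):
            raise DomainError(f"method must be 'ols' or 'pls', got {self.method!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if "test_ids" in payload and payload["test_ids"] is not None:
            payload["test_ids"] = frozenset(payload["test_ids"])
        return cls(**payload)


def _fit(config: RunConfig, X: pd.DataFrame, y: np.ndarray) -> QSARModel:
    if config.method == "pls":
        k = len([c for c in X.columns if c != "compound_id"])
        return fit_pls(X, y, n_components=config.n_components or k)
    return fit_ols(X, y)


def _fitter_for(config: RunConfig):
    if config.method == "pls":
        return fit_pls, {"n_components": config.n_components or 4}
    return fit_ols, {}


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_reproduce(config: RunConfig | None = None) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict with the in-memory results and artifact paths; the
    ``ok`` entry is True iff the reliability gate passes and (when the
    originally reported predictions are available) the per-compound
    concordance bound of 0.01 μM holds.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.descriptors_path:
        descriptors = d.read_table(config.descriptors_path, "descriptors")
    else:
        descriptors = d.load_fixture("descriptors")
    if config.cytotoxicity_path:
        cytotox = d.read_table(config.cytotoxicity_path, "cytotoxicity")
    else:
        cytotox = d.load_fixture("cytotoxicity")
    using_fixtures = not (config.descriptors_path or config.cytotoxicity_path)
    printed_rf = d.load_fixture("reversal_printed") if using_fixtures else None
    printed_qsar = d.load_fixture("qsar_printed") if using_fixtures else None
    logger.info("loaded tables: %d descriptor rows, %d cytotoxicity records",
                len(descriptors), len(cytotox))

    rev = reversal_table(cytotox, printed=printed_rf)
    rev_path = out / "reversal_report.csv"
    rev.to_csv(rev_path, index=False)
    logger.info("reversal statistics: %d treatments", len(rev))

    responses = d.response_table(cytotox)
    split = (
        d.SplitSpec.default()
        if config.test_ids is None
        else d.SplitSpec.from_test_ids(config.test_ids, set(responses["compound_id"]))
    )
    tables = d.split_train_test(descriptors, responses, split)
    y_train = tables.train_response["ic50"].to_numpy()
    y_test = tables.test_response["ic50"].to_numpy()
    logger.info("split: %d train / %d test", len(y_train), len(y_test))

    corr = pearson_matrix(y_train, tables.train_descriptors.drop(columns="compound_id"))
    corr.to_frame().to_csv(out / "correlation_report.csv")
    screen = collinearity_filter(corr, threshold=config.collinearity_threshold)
    _write_json(
        {
            "selected": screen.selected,
            "dropped_for_collinearity": [
                {"pair": list(pair), "r": r} for pair, r in screen.dropped_for_collinearity
            ],
            "log": screen.log,
        },
        out / "selection_log.json",
    )

    model = _fit(config, tables.train_descriptors, y_train)
    model.to_json(out / "model.json")

    fitter, fkw = _fitter_for(config)
    report = validate_model(
        model, tables.train_descriptors, y_train,
        tables.test_descriptors if len(y_test) else None,
        y_test if len(y_test) else None,
        fitter=fitter, **fkw,
    )
    _write_json(report.to_dict(), out / "validation_report.json")

    resid = residual_table(model, descriptors, _aligned_response(descriptors, responses), split)
    concordance_ok = None
    max_delta = None
    if printed_qsar is not None:
        merged = resid.merge(printed_qsar[["compound_id", "ic50_predicted"]]
                             .rename(columns={"ic50_predicted": "reported_predicted"}),
                             on="compound_id")
        resid["delta_vs_reported"] = merged["ic50_predicted"] - merged["reported_predicted"]
        max_delta = float(resid["delta_vs_reported"].abs().max())
        concordance_ok = bool(max_delta <= CONCORDANCE_TOL)
    resid_path = out / "residuals_report.csv"
    resid.to_csv(resid_path, index=False)

    equation = format_equation(model)
    n_inhib = int((rev["classification"] == "potential_inhibitor").sum())
    flagged = (
        rev.loc[rev.get("inconsistent", pd.Series(False, index=rev.index)).fillna(False),
                "treatment_id"].tolist()
        if "inconsistent" in rev.columns
        else []
    )
    lines = [
        "flavopgp reproduction run",
        "=========================",
        f"treatments analysed: {len(rev)} "
        f"(potential inhibitors: {n_inhib}; printed-vs-recomputed flags: {flagged})",
        f"training/test split: {len(y_train)}/{len(y_test)}",
        f"model ({model.method}): {equation}",
        (
            f"R2 = {report.r2:.3f}, R2_adj = {report.r2_adj:.3f}, "
            f"RMSE = {report.rmse:.3f} uM, F = {report.f_stat:.3f}, "
            f"p = {report.p_value:.3g}, Q2_LOO = {report.q2_loo:.3f}, "
            + (f"R2_pred = {report.r2_pred:.3f}" if report.r2_pred is not None
               else "R2_pred = unavailable")
        ),
        f"reliability gate: {report.gate}"
        + (f" ({'; '.join(report.gate_reasons)})" if report.gate_reasons else ""),
    ]
    if max_delta is not None:
        lines.append(
            f"max |predicted - reported| over {len(resid)} compounds: "
            f"{max_delta:.3f} uM ({'within' if concordance_ok else 'EXCEEDS'} "
            f"{CONCORDANCE_TOL} uM)"
        )
    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary, encoding="utf-8")

    ok = report.gate == "reliable" and (concordance_ok is not False)
    return {
        "ok": ok,
        "model": model,
        "report": report,
        "reversal": rev,
        "correlation": corr,
        "residuals": resid,
        "equation": equation,
        "concordance_ok": concordance_ok,
        "max_delta": max_delta,
        "summary": summary,
        "out_dir": str(out),
    }


def _aligned_response(descriptors: pd.DataFrame, responses: pd.DataFrame) -> np.ndarray:
    merged = descriptors[["compound_id"]].merge(responses, on="compound_id", how="left")
    if merged["ic50"].isna().any():
        missing = merged.loc[merged["ic50"].isna(), "compound_id"].tolist()
        raise DomainError(f"no response for compound(s) {missing}")
    return merged["ic50"].to_numpy()


def run_simulate(spec: SyntheticSpec, config: RunConfig | None = None) -> dict:
    """Generate a synthetic dataset from ``spec``, run the fit/validation
    chain on it, and add a ground-truth-vs-estimate recovery table."""
    config = config or RunConfig(out_dir="flavopgp_sim")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    X_train = gen_descriptor_matrix(spec)
    y_train = gen_response(
        X_train, spec.true_coefficients, spec.true_intercept, spec.noise_sd, spec.seed
    )
    test_spec = spec.with_(n_compounds=max(7, spec.n_compounds // 3), seed=spec.seed + 1)
    X_test = gen_descriptor_matrix(test_spec)
    y_test = gen_response(
        X_test, spec.true_coefficients, spec.true_intercept, spec.noise_sd, test_spec.seed
    )

    X_train.to_csv(out / "synthetic_descriptors.csv", index=False)
    pd.DataFrame({"compound_id": X_train["compound_id"], "ic50": y_train}).to_csv(
        out / "synthetic_response.csv", index=False
    )

    model = _fit(config, X_train, y_train)
    model.to_json(out / "model.json")
    fitter, fkw = _fitter_for(config)
    report = validate_model(model, X_train, y_train, X_test, y_test, fitter=fitter, **fkw)
    _write_json(report.to_dict(), out / "validation_report.json")

    recovery = pd.DataFrame(
        {
            "term": list(model.descriptor_names) + ["intercept"],
            "true": list(np.asarray(spec.true_coefficients)) + [spec.true_intercept],
            "estimate": list(model.coefficients) + [model.intercept],
        }
    )
    recovery["error"] = recovery["estimate"] - recovery["true"]
    recovery.to_csv(out / "recovery_table.csv", index=False)

    summary = (
        f"flavopgp simulation run (seed {spec.seed}, n {spec.n_compounds}, "
        f"noise_sd {spec.noise_sd})\n"
        f"model: {format_equation(model)}\n"
        f"max |coefficient error|: {recovery['error'].abs().max():.4f}\n"
        f"gate: {report.gate}\n"
    )
    (out / "summary.txt").write_text(summary, encoding="utf-8")
    return {
        "ok": report.gate == "reliable",
        "model": model,
        "report": report,
        "recovery": recovery,
        "summary": summary,
        "out_dir": str(out),
    }


def run_predict(model_path: str | Path, descriptors_path: str | Path,
                out_path: str | Path) -> pd.DataFrame:
    """Score a descriptor CSV with a saved model; deterministic, one row in,
    one prediction out.  Rows with missing or non-numeric descriptor values
    raise a :class:`ParseError` carrying the row location."""
    model = QSARModel.from_json(model_path)
    raw = pd.read_csv(descriptors_path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in model.descriptor_names if c not in raw.columns]
    if missing:
        raise ParseError(f"{descriptors_path}: missing column(s) {missing}")
    values = np.empty((len(raw), len(model.descriptor_names)))
    for j, col in enumerate(model.descriptor_names):
        for i, cell in enumerate(raw[col].tolist()):
            values[i, j] = d._parse_float(cell, i + 2, col)
    preds = predict(model, values) if len(raw) else np.array([])
    out = pd.DataFrame(
        {
            "compound_id": raw["compound_id"] if "compound_id" in raw.columns
            else np.arange(1, len(raw) + 1),
            "predicted_ic50": preds,
        }
    )
    out.to_csv(out_path, index=False)
    return out
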