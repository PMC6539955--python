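"""Model-quality statistics and reliability gates for the QSAR fit.

Definitions (n training rows, k descriptors):

* ``R² = 1 − SSE/SST``; ``R²_adj = 1 − (1−R²)(n−1)/(n−k−1)``
* ``RMSE = sqrt(SSE/(n−k−1))`` — residual degrees of freedom in the
  denominator, matching a regression standard error of estimate
* ``F = (R²/k) / ((1−R²)/(n−k−1))`` with p from F(k, n−k−1)
* ``Q²(LOO) = 1 − PRESS/SST`` where each held-out row is predicted by a
  model refit on the other n−1 rows and SST is taken about the mean of
  *all* n training responses
* ``R²_pred`` — squared Pearson correlation between observed and predicted
  IC50 on the external test set (NOT the PRESS-based ``1 − PRESS/SD`` form,
  which gives a different number; see :func:`r2_pred_press`)

A model passes the reliability gate iff Q² > 0.5 and R²_pred > 0.6, both
strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data import SplitSpec
from .errors import FitError, UndefinedStatisticError
from .qsar import QSARModel, fit_ols, predict

__all__ = [
    "ValidationReport",
    "fit_statistics",
    "q2_loo",
    "r2_pred",
    "r2_pred_press",
    "reliability_gate",
    "residual_table",
    "validate_model",
]

GATE_RELIABLE = "reliable"
GATE_UNRELIABLE = "unreliable"


@dataclass
class ValidationReport:
    r2: float | None = None
    r2_adj: float | None = None
    rmse: float | None = None
    f_stat: float | None = None
    p_value: float | None = None
    q2_loo: float | None = None
    r2_pred: float | None = None
    gate: str | None = None
    gate_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "rmse": self.rmse,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "q2_loo": self.q2_loo,
            "r2_pred": self.r2_pred,
            "gate": self.gate,
            "gate_reasons": list(self.gate_reasons),
        }


def fit_statistics(
    model: QSARModel, X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series
) -> ValidationReport:
    """Training-set goodness-of-fit statistics for a fitted model."""
    yv = np.asarray(y, dtype=float)
    yhat = predict(model, X)
    n, k = len(yv), len(model.descriptor_names)
    if n <= k + 1:
        raise FitError(f"insufficient data: n={n} <= k+1={k + 1}")
    sse = float(((yv - yhat) ** 2).sum())
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("zero response variance")
    r2 = 1.0 - sse / sst
    dof = n - k - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    rmse = float(np.sqrt(sse / dof))
    denom = (1.0 - r2) / dof
    f_stat = float("inf") if denom == 0 else (r2 / k) / denom
    p_value = float(stats.f.sf(f_stat, k, dof)) if np.isfinite(f_stat) else 0.0
    return ValidationReport(
        r2=r2, r2_adj=r2_adj, rmse=rmse, f_stat=float(f_stat), p_value=p_value
    )


def q2_loo(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    fitter: Callable[..., QSARModel] = fit_ols,
    **fitter_kwargs,
) -> float:
    """Leave-one-out cross-validated Q².

    Each training row is predicted by a model refit (with ``fitter``) on the
    remaining rows; Q² = 1 − Σ(yᵢ−ŷ₍₋ᵢ₎)² / Σ(yᵢ−ȳ)² with ȳ the mean over
    all n rows.
    """
    if isinstance(X, pd.DataFrame):
        Xdf = X.reset_index(drop=True)
        take = lambda m: Xdf.loc[m].reset_index(drop=True)
        row = lambda i: Xdf.iloc[[i]]
    else:
        arr = np.asarray(X, dtype=float)
        take = lambda m: arr[m]
        row = lambda i: arr[[i]]
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 3:
        raise FitError(f"need at least 3 rows for LOO, got {n}")
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedStatisticError("zero response variance: Q² undefined")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub_model = fitter(take(mask), yv[mask], **fitter_kwargs)
        press += float((yv[i] - predict(sub_model, row(i))[0]) ** 2)
    return 1.0 - press / sst


def r2_pred(
    model: QSARModel, X_test: pd.DataFrame | np.ndarray, y_test: np.ndarray | pd.Series
) -> float:
    """External predictivity: squared Pearson correlation between observed
    and predicted response on the test set (needs >= 3 rows)."""
    yv = np.asarray(y_test, dtype=float)
    if len(yv) < 3:
        raise FitError(f"need at least 3 test rows, got {len(yv)}")
    yhat = predict(model, X_test)
    if np.std(yhat) == 0 or np.std(yv) == 0:
        raise UndefinedStatisticError("constant predictions or responses")
    r = float(np.corrcoef(yv, yhat)[0, 1])
    return r * r


def r2_pred_press(
    model: QSARModel,
    X_test: pd.DataFrame | np.ndarray,
    y_test: np.ndarray | pd.Series,
    y_train_mean: float,
) -> float:
    """PRESS-based external statistic 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)².

    Provided for comparison only: it is a different quantity from the
    squared-Pearson :func:`r2_pred` and is *not* the headline external
    statistic of this pipeline.
    """
    yv = np.asarray(y_test, dtype=float)
    yhat = predict(model, X_test)
    press = float(((yv - yhat) ** 2).sum())
    sd = float(((yv - y_train_mean) ** 2).sum())
    if sd == 0:
        raise UndefinedStatisticError("test responses all equal the training mean")
    return 1.0 - press / sd


def reliability_gate(report: ValidationReport) -> ValidationReport:
    """Apply the acceptance gate: Q² > 0.5 and R²_pred > 0.6, both strict."""
    reasons: list[str] = []
    if report.q2_loo is None:
        reasons.append("Q² unavailable")
    elif not report.q2_loo > 0.5:
        reasons.append(f"Q² not > 0.5 (got {report.q2_loo:.3f})")
    if report.r2_pred is None:
        reasons.append("R²_pred unavailable (no external test set)")
    elif not report.r2_pred > 0.6:
        reasons.append(f"R²_pred not > 0.6 (got {report.r2_pred:.3f})")
    report.gate = GATE_RELIABLE if not reasons else GATE_UNRELIABLE
    report.gate_reasons = reasons
    return report


def residual_table(
    model: QSARModel,
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Per-compound experimental vs predicted IC50 with residuals.

    Covers every row of ``X`` (training and test alike); if a split spec is
    given, a ``split_role`` column marks each compound's role.
    """
    yv = np.asarray(y, dtype=float)
    yhat = predict(model, X)
    out = pd.DataFrame(
        {
            "compound_id": X["compound_id"].to_numpy()
            if "compound_id" in X.columns
            else np.arange(1, len(yv) + 1),
            "ic50_experimental": yv,
            "ic50_predicted": yhat,
            "residual": yv - yhat,
        }
    )
    if split is not None:
        out["split_role"] = [
            "test" if cid in split.test_ids else "train" for cid in out["compound_id"]
        ]
    return out


def validate_model(
    model: QSARModel,
    X_train: pd.DataFrame | np.ndarray,
    y_train: np.ndarray | pd.Series,
    X_test: pd.DataFrame | np.ndarray | None = None,
    y_test: np.ndarray | pd.Series | None = None,
    fitter: Callable[..., QSARModel] = fit_ols,
    **fitter_kwargs,
) -> ValidationReport:
    """Full report: fit statistics, LOO Q², external R²_pred and the gate."""
    report = fit_statistics(model, X_train, y_train)
    report.q2_loo = q2_loo(X_train, y_train, fitter=fitter, **fitter_kwargs)
    if X_test is not None and y_test is not None and len(np.asarray(y_test)) >= 3:
        report.r2_pred = r2_pred(model, X_test, y_test)
    return reliability_gate(report)
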