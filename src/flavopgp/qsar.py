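"""Linear QSAR model: OLS and PLS (NIPALS) fits, prediction, rendering.

The model relates the KB/MDR1 daunorubicin IC50 (μM) linearly to four 2D
descriptors.  Two fitters are provided:

* :func:`fit_ols` — ordinary least squares with intercept;
* :func:`fit_pls` — PLS1 by the NIPALS algorithm on autoscaled descriptors
  (mean 0, SD 1), with coefficients back-transformed to the raw descriptor
  scale.  With as many latent components as descriptors, PLS reproduces the
  OLS solution; the component count is configurable.

Coefficients are always reported on the raw descriptor scale so the fitted
equation reads directly in descriptor units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FitError

__all__ = ["QSARModel", "fit_ols", "fit_pls", "predict", "format_equation"]


@dataclass(frozen=True)
class QSARModel:
    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]  # μM per descriptor unit
    intercept: float                 # μM
    method: str                      # "ols" | "pls"
    n_components: int | None = None  # pls only
    training_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.descriptor_names):
            raise DomainError("one coefficient per descriptor required")
        if self.method == "pls":
            k = len(self.descriptor_names)
            if self.n_components is None or not (1 <= self.n_components <= k):
                raise DomainError(f"n_components must be in [1, {k}]")

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "method": self.method,
            "n_components": self.n_components,
            "training_ids": list(self.training_ids) if self.training_ids else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_dict(cls, payload: dict) -> "QSARModel":
        return cls(
            descriptor_names=tuple(payload["descriptor_names"]),
            coefficients=tuple(payload["coefficients"]),
            intercept=float(payload["intercept"]),
            method=payload["method"],
            n_components=payload.get("n_components"),
            training_ids=tuple(payload["training_ids"]) if payload.get("training_ids") else None,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "QSARModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...], np.ndarray | None]:
    if isinstance(X, pd.DataFrame):
        names = tuple(c for c in X.columns if c != "compound_id")
        ids = X["compound_id"].to_numpy() if "compound_id" in X.columns else None
        return X[list(names)].to_numpy(dtype=float), names, ids
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"x{i + 1}" for i in range(arr.shape[1])), None


def fit_ols(X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series) -> QSARModel:
    """Ordinary least squares with intercept; requires full column rank and
    n > k + 1 so residual degrees of freedom remain for inference."""
    mat, names, ids = _design(X)
    yv = np.asarray(y, dtype=float)
    n, k = mat.shape
    if n <= k + 1:
        raise FitError(f"need n > k + 1 (got n={n}, k={k})")
    A = np.column_stack([mat, np.ones(n)])
    beta, _, rank, _ = np.linalg.lstsq(A, yv, rcond=None)
    if rank < k + 1:
        raise FitError("singular design: descriptor columns are linearly dependent")
    return QSARModel(
        descriptor_names=names,
        coefficients=tuple(float(b) for b in beta[:k]),
        intercept=float(beta[k]),
        method="ols",
        training_ids=tuple(int(i) for i in ids) if ids is not None else None,
    )


def fit_pls(
    X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series, n_components: int
) -> QSARModel:
    """PLS1 regression by NIPALS on autoscaled descriptors.

    Latent components are extracted from the standardised descriptor block
    (weights from the X'y covariance, deflation of X by each score/loading
    pair); the regression vector is back-transformed so that coefficients
    and intercept apply to raw descriptor values.
    """
    mat, names, ids = _design(X)
    yv = np.asarray(y, dtype=float)
    n, k = mat.shape
    if not 1 <= n_components <= k:
        raise DomainError(f"n_components must be in [1, {k}], got {n_components}")
    x_mean, x_sd = mat.mean(axis=0), mat.std(axis=0, ddof=1)
    if (x_sd == 0).any():
        dead = [names[i] for i in np.flatnonzero(x_sd == 0)]
        raise FitError(f"zero-variance column(s) {dead}: cannot autoscale")
    Xc = (mat - x_mean) / x_sd
    y_mean = yv.mean()
    yc = yv - y_mean

    W = np.zeros((k, n_components))
    P = np.zeros((k, n_components))
    q = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # no covariance left to model; truncate
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        W[:, a], P[:, a], q[a] = w, p, q_a
        Xd -= np.outer(t, p)
        yd -= q_a * t

    b_scaled = W @ np.linalg.solve(P.T @ W, q) if W.shape[1] else np.zeros(k)
    coef = b_scaled / x_sd
    intercept = float(y_mean - coef @ x_mean)
    return QSARModel(
        descriptor_names=names,
        coefficients=tuple(float(c) for c in coef),
        intercept=intercept,
        method="pls",
        n_components=n_components,
        training_ids=tuple(int(i) for i in ids) if ids is not None else None,
    )


def predict(model: QSARModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted IC50 (μM): X · coefficients + intercept."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.descriptor_names if c not in X.columns]
        if missing:
            raise DomainError(f"descriptor column(s) {missing} absent from input")
        mat = X[list(model.descriptor_names)].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat.reshape(1, -1)
        if mat.shape[1] != len(model.descriptor_names):
            raise DomainError(
                f"expected {len(model.descriptor_names)} columns, got {mat.shape[1]}"
            )
    return mat @ np.asarray(model.coefficients) + model.intercept


def format_equation(model: QSARModel, decimals: int = 3, response: str = "IC50") -> str:
    """Render the fitted equation with signs folded into the operators,
    e.g. ``IC50 = 0.183vsurf_DW23 - 0.359e_sol + ... - 9.859``.

    Zero coefficients are kept (rendered ``+ 0.000name``), so the term
    structure of the model is always visible.
    """
    parts: list[str] = []
    for i, (name, c) in enumerate(zip(model.descriptor_names, model.coefficients)):
        mag = f"{abs(c):.{decimals}f}{name}"
        if i == 0:
            parts.append(mag if c >= 0 else f"-{mag}")
        else:
            parts.append(f"{'-' if c < 0 else '+'} {mag}")
    b0 = model.intercept
    parts.append(f"{'-' if b0 < 0 else '+'} {abs(b0):.{decimals}f}")
    return f"{response} = " + " ".join(parts)
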