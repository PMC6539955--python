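"""Descriptor screening: correlation analysis and stepwise MLR selection.

Three stages mirror standard 2D-QSAR practice:

1. a Pearson product-moment correlation matrix between the response and the
   candidate descriptors, with two-tailed significance stars
   (``*`` p < 0.05, ``**`` p < 0.01) from the t-statistic
   ``t = r sqrt(n-2) / sqrt(1 - r^2)``;
2. a pairwise collinearity filter that greedily removes descriptors until
   every inter-descriptor |r| is below a threshold (default 0.5), dropping
   from each offending pair the member less correlated with the response;
3. classical forward-entry / backward-removal stepwise multiple linear
   regression on partial F-tests (enter at p < 0.05, remove at p > 0.10 by
   default), deterministic under a lower-p-then-lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedStatisticError

__all__ = [
    "CorrelationMatrix",
    "SelectionResult",
    "pearson_matrix",
    "collinearity_filter",
    "stepwise_mlr_select",
]

STAR_NONE, STAR_P05, STAR_P01 = "", "*", "**"


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]          # response first, then descriptors
    r: np.ndarray                    # symmetric, unit diagonal
    p_values: np.ndarray             # two-tailed; diagonal 0
    stars: np.ndarray                # "", "*", "**"
    n: int

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Upper-triangular display table with significance stars."""
        cells = np.full(self.r.shape, "", dtype=object)
        for i in range(len(self.labels)):
            for j in range(i, len(self.labels)):
                cells[i, j] = f"{self.r[i, j]:.{decimals}f} {self.stars[i, j]}".rstrip()
        return pd.DataFrame(cells, index=list(self.labels), columns=list(self.labels))

    def lookup(self, a: str, b: str) -> tuple[float, str]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.r[i, j]), str(self.stars[i, j])


@dataclass
class SelectionResult:
    selected: list[str] = field(default_factory=list)
    entry_stats: list[dict] = field(default_factory=list)
    dropped_for_collinearity: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _star(p: float) -> str:
    if p < 0.01:
        return STAR_P01
    if p < 0.05:
        return STAR_P05
    return STAR_NONE


def pearson_matrix(
    response: pd.Series | np.ndarray,
    descriptors: pd.DataFrame,
    ids: set[int] | None = None,
    response_label: str = "IC50",
) -> CorrelationMatrix:
    """Correlations between the response and every descriptor column.

    ``ids`` restricts the computation to the rows whose ``compound_id``
    is in the set (the table must then carry that column); by default all
    rows are used.  Significance stars use the exact two-tailed t-test
    at the sample size actually used.
    """
    desc = descriptors
    resp = pd.Series(np.asarray(response, dtype=float))
    if ids is not None:
        if "compound_id" not in desc.columns:
            raise DomainError("ids given but descriptor table has no compound_id column")
        mask = desc["compound_id"].isin(ids).to_numpy()
        desc = desc.loc[mask]
        resp = resp.loc[mask]
    cols = [c for c in desc.columns if c != "compound_id"]
    mat = np.column_stack([resp.to_numpy()] + [desc[c].to_numpy(dtype=float) for c in cols])
    n = mat.shape[0]
    if n < 3:
        raise DomainError(f"need at least 3 rows for a correlation, got {n}")
    sds = mat.std(axis=0)
    for label, sd in zip([response_label] + cols, sds):
        if sd == 0:
            raise UndefinedStatisticError(f"column {label!r} is constant; correlation undefined")

    k = mat.shape[1]
    r = np.corrcoef(mat.T)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij = np.clip(r[i, j], -1.0, 1.0)
            t = rij * np.sqrt(n - 2) / np.sqrt(max(1.0 - rij**2, 1e-300))
            p[i, j] = p[j, i] = 2.0 * stats.t.sf(abs(t), n - 2)
    stars = np.vectorize(_star)(p).astype(object)
    np.fill_diagonal(stars, STAR_NONE)
    return CorrelationMatrix(
        labels=tuple([response_label] + cols), r=r, p_values=p, stars=stars, n=n
    )


def collinearity_filter(matrix: CorrelationMatrix, threshold: float = 0.5) -> SelectionResult:
    """Greedily remove descriptors until all inter-descriptor |r| < threshold.

    For each pair at or above the threshold (worst first), the member with
    the weaker absolute correlation to the response is dropped; ties break
    lexicographically.
    """
    labels = list(matrix.labels)
    keep = list(range(1, len(labels)))  # descriptor indices; 0 is the response
    result = SelectionResult()
    while True:
        worst = None
        for a_pos, i in enumerate(keep):
            for j in keep[a_pos + 1:]:
                rij = abs(matrix.r[i, j])
                if rij >= threshold and (worst is None or rij > worst[0]):
                    worst = (rij, i, j)
        if worst is None:
            break
        rij, i, j = worst
        # drop the member less correlated with the response
        ri, rj = abs(matrix.r[0, i]), abs(matrix.r[0, j])
        if ri < rj or (ri == rj and labels[i] > labels[j]):
            drop = i
        else:
            drop = j
        keep.remove(drop)
        result.dropped_for_collinearity.append(((labels[i], labels[j]), float(matrix.r[i, j])))
        result.log.append(
            f"dropped {labels[drop]}: |r|={rij:.3f} with "
            f"{labels[i] if drop == j else labels[j]} >= {threshold}"
        )
    result.selected = [labels[i] for i in keep]
    return result


def _partial_f_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-tailed p-value of each coefficient's partial F (= squared t) test
    in the OLS fit of y on X plus an intercept."""
    n, k = X.shape
    A = np.column_stack([X, np.ones(n)])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k + 1:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - A @ beta
    sse = float(resid @ resid)
    df = n - k - 1
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    if sse < 1e-12:  # perfect fit: every term maximally significant
        return np.zeros(k)
    cov = sse / df * np.linalg.inv(A.T @ A)
    t = beta[:k] / np.sqrt(np.diag(cov)[:k])
    return 2.0 * stats.t.sf(np.abs(t), df)


def stepwise_mlr_select(
    pool: pd.DataFrame,
    response: pd.Series | np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> SelectionResult:
    """Forward-entry / backward-removal stepwise MLR on partial F-tests.

    At each forward step the candidate with the smallest partial-F p-value
    enters if p < ``p_enter``; after each entry, in-model terms with
    p > ``p_remove`` are removed (largest p first).  Candidates that make
    the design rank-deficient are skipped with a logged reason.  The
    procedure is deterministic: ties break on lower p then lexicographic
    column name, so the outcome does not depend on pool column order.
    """
    if not p_enter < p_remove:
        raise DomainError(f"p_enter ({p_enter}) must be < p_remove ({p_remove})")
    y = np.asarray(response, dtype=float)
    cols = [c for c in pool.columns if c != "compound_id"]
    X = {c: pool[c].to_numpy(dtype=float) for c in cols}
    result = SelectionResult()
    model: list[str] = []

    while True:
        # forward entry
        best: tuple[float, str] | None = None
        for c in sorted(set(cols) - set(model)):
            try:
                p = _partial_f_pvalues(
                    np.column_stack([X[m] for m in model] + [X[c]]), y
                )[-1]
            except np.linalg.LinAlgError as exc:
                result.log.append(f"skipped {c}: {exc}")
                continue
            if best is None or (p, c) < best:
                best = (float(p), c)
        if best is None or best[0] >= p_enter:
            break
        p_in, entered = best
        model.append(entered)
        df = len(y) - len(model) - 1
        f_in = float(stats.f.isf(p_in, 1, df)) if 0 < p_in < 1 else float("inf")
        result.entry_stats.append(
            {"step": len(result.entry_stats) + 1, "entered": entered, "p": p_in, "F": f_in}
        )
        result.log.append(f"entered {entered} (p={p_in:.4g})")

        # backward removal
        while len(model) > 1:
            ps = _partial_f_pvalues(np.column_stack([X[m] for m in model]), y)
            worst_i = int(np.argmax(ps))
            if ps[worst_i] <= p_remove:
                break
            removed = model.pop(worst_i)
            result.log.append(f"removed {removed} (p={ps[worst_i]:.4g})")

        # perfect fit: nothing left to explain
        A = np.column_stack([X[m] for m in model] + [np.ones(len(y))])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        if float(resid @ resid) < 1e-12:
            result.log.append("perfect fit reached; selection stopped")
            break

    result.selected = list(model)
    return result
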