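"""Multidrug-resistance reversal-fold statistics.

Three fold ratios summarise how a co-treatment modulates daunorubicin
cytotoxicity:

* ``rf_mdr1`` — IC50 in KB/MDR1 cells without the co-treatment over IC50 with
  it (reversal in the P-gp-overexpressing line);
* ``rf_kb`` — the same ratio in the parental KB line;
* ``rf_cross`` — cross-resistance: KB/MDR1 IC50 over KB IC50 under the same
  treatment.

A compound with rf_mdr1 strictly greater than 1.000 is a potential P-gp
inhibitor; strictly below, a potential activator.  Folds are always
recomputed from the IC50 means; originally reported fold columns are used
only as expectations, and rows where they disagree with the recomputed
ratios beyond print rounding are flagged rather than corrected.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConsistencyError, DomainError

__all__ = [
    "reversal_fold",
    "cross_resistance_fold",
    "classify_inhibitor",
    "reversal_table",
]

#: largest |recomputed - printed| attributable to three-decimal rounding
DEFAULT_FLAG_TOLERANCE = 0.005

POTENTIAL_INHIBITOR = "potential_inhibitor"
POTENTIAL_ACTIVATOR = "potential_activator"
NEUTRAL = "neutral"


def reversal_fold(ic50_without_inhibitor: float, ic50_with_inhibitor: float) -> float:
    """Fold change in drug potency caused by a co-treatment (same cell line)."""
    if ic50_without_inhibitor <= 0 or ic50_with_inhibitor <= 0:
        raise DomainError("IC50 values must be positive")
    return ic50_without_inhibitor / ic50_with_inhibitor


def cross_resistance_fold(ic50_mdr1: float, ic50_kb: float) -> float:
    """Resistance of the P-gp line relative to the parental line (same treatment)."""
    if ic50_mdr1 <= 0 or ic50_kb <= 0:
        raise DomainError("IC50 values must be positive")
    return ic50_mdr1 / ic50_kb


def classify_inhibitor(rf_mdr1: float) -> str:
    """Classify by the KB/MDR1 reversal fold with a strict 1.000 threshold."""
    if rf_mdr1 <= 0:
        raise DomainError("reversal fold must be positive")
    if rf_mdr1 > 1.0:
        return POTENTIAL_INHIBITOR
    if rf_mdr1 < 1.0:
        return POTENTIAL_ACTIVATOR
    return NEUTRAL


def reversal_table(
    cytotox: pd.DataFrame,
    printed: pd.DataFrame | None = None,
    flag_tolerance: float = DEFAULT_FLAG_TOLERANCE,
) -> pd.DataFrame:
    """Compute all three folds per treatment from IC50 means.

    One row per treatment (negative control, positive control, then each
    compound), with a classification column.  If a table of originally
    reported folds is given, per-column deltas and an ``inconsistent`` flag
    (any |delta| > ``flag_tolerance``) are attached.
    """
    need = {"treatment_id", "cell_line", "ic50_mean"}
    if not need <= set(cytotox.columns):
        raise ConsistencyError(f"cytotoxicity table must have columns {sorted(need)}")

    wide = cytotox.pivot(index="treatment_id", columns="cell_line", values="ic50_mean")
    if "KB" not in wide.columns or "KB_MDR1" not in wide.columns:
        raise ConsistencyError("both KB and KB_MDR1 records required")
    if "negative_control" not in wide.index:
        raise ConsistencyError("missing negative control records")
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ConsistencyError(f"treatments missing one cell line: {bad}")

    ctrl_mdr1 = float(wide.loc["negative_control", "KB_MDR1"])
    ctrl_kb = float(wide.loc["negative_control", "KB"])

    order = [t for t in ("negative_control", "elacridar") if t in wide.index]
    order += sorted((t for t in wide.index if t not in order), key=lambda t: int(t))

    rows = []
    for tid in order:
        m, k = float(wide.loc[tid, "KB_MDR1"]), float(wide.loc[tid, "KB"])
        rf_m = reversal_fold(ctrl_mdr1, m)
        rf_k = reversal_fold(ctrl_kb, k)
        rows.append(
            {
                "treatment_id": tid,
                "ic50_mdr1": m,
                "ic50_kb": k,
                "rf_mdr1": rf_m,
                "rf_kb": rf_k,
                "rf_cross": cross_resistance_fold(m, k),
                "classification": classify_inhibitor(rf_m),
            }
        )
    out = pd.DataFrame(rows)

    if printed is not None:
        merged = out.merge(
            printed, on="treatment_id", how="left", suffixes=("", "_printed")
        )
        for col in ("rf_mdr1", "rf_kb", "rf_cross"):
            out[f"delta_{col}"] = merged[col] - merged[f"{col}_printed"]
        deltas = out[["delta_rf_mdr1", "delta_rf_kb", "delta_rf_cross"]].abs()
        out["inconsistent"] = deltas.gt(flag_tolerance).any(axis=1)
    return out
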