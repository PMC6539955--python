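"""Study tables, CSV schemas, and the fixed train/test split.

The bundled dataset covers 31 dietary flavonoids assayed for their effect on
daunorubicin cytotoxicity in a parental KB carcinoma line and its
P-glycoprotein-overexpressing KB/MDR1 transfectant, together with four 2D
molecular descriptors per compound (vsurf_DW23, E_sol, dipole, vsurf_G) and
the published model predictions.  All tables are shipped as plain CSV at the
precision they were originally reported (three decimals; values are loaded
verbatim, never re-rounded).

Schemas are strict: UTF-8, comma separator, ``.`` decimal mark, mandatory
header.  A decimal comma or any other non-numeric cell is a :class:`ParseError`
naming the offending row and column, never a silent misread.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FixtureIntegrityError, ParseError

__all__ = [
    "SCAFFOLDS",
    "SUBSTITUENT_CODES",
    "SUBSTITUENT_POSITIONS",
    "CELL_LINES",
    "SplitSpec",
    "TrainTestTables",
    "load_fixture",
    "read_table",
    "write_table",
    "split_train_test",
    "response_table",
    "parse_substituents",
]

SCAFFOLDS = frozenset(
    {"flavone", "flavanone", "flavanonol-like", "isoflavone", "flavonolignan"}
)
SUBSTITUENT_CODES = frozenset({"OH", "OMe", "H", "Cglc", "Carb", "ORG"})
SUBSTITUENT_POSITIONS = frozenset({"3", "5", "6", "7", "8", "2'", "3'", "4'", "5'"})
CELL_LINES = frozenset({"KB", "KB_MDR1"})
CONTROL_TREATMENTS = frozenset({"negative_control", "elacridar"})

ALL_COMPOUND_IDS = frozenset(range(1, 32))
DEFAULT_TEST_IDS = frozenset({2, 4, 9, 20, 22, 27, 30})

DESCRIPTOR_NAMES = ("vsurf_DW23", "e_sol", "dipole", "vsurf_G")

_FLOAT_RE = re.compile(r"^-?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_INT_RE = re.compile(r"^\d+$")


def _parse_float(cell: str, row: int, column: str) -> float:
    cell = cell.strip()
    if "," in cell:
        raise ParseError(
            f"row {row}, column {column!r}: {cell!r} contains a comma; "
            "decimal commas are not accepted (use '.')"
        )
    if not _FLOAT_RE.match(cell):
        raise ParseError(f"row {row}, column {column!r}: {cell!r} is not numeric")
    return float(cell)


def _parse_int(cell: str, row: int, column: str) -> int:
    cell = cell.strip()
    if not _INT_RE.match(cell):
        raise ParseError(f"row {row}, column {column!r}: {cell!r} is not an integer")
    return int(cell)


def parse_substituents(text: str) -> dict[str, str]:
    """Parse a ``pos:code;pos:code`` substituent string into a mapping.

    Positions come from the flavonoid ring numbering {3,5,6,7,8,2',3',4',5'}
    and codes from the closed set {OH, OMe, H, Cglc, Carb, ORG}.
    """
    if not text or not text.strip():
        return {}
    out: dict[str, str] = {}
    for item in text.split(";"):
        pos, _, code = item.strip().partition(":")
        if pos not in SUBSTITUENT_POSITIONS:
            raise ParseError(f"substituent position {pos!r} not in {sorted(SUBSTITUENT_POSITIONS)}")
        if code not in SUBSTITUENT_CODES:
            raise ParseError(f"substituent code {code!r} not in {sorted(SUBSTITUENT_CODES)}")
        out[pos] = code
    return out


def format_substituents(subs: Mapping[str, str]) -> str:
    return ";".join(f"{p}:{c}" for p, c in subs.items())


# --------------------------------------------------------------------------
# schemas

@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    int_columns: tuple[str, ...] = ()
    float_columns: tuple[str, ...] = ()
    key_columns: tuple[str, ...] = ()
    validator: Callable[[pd.DataFrame], None] | None = None


def _validate_compounds(df: pd.DataFrame) -> None:
    ids = df["compound_id"]
    if set(ids) != ALL_COMPOUND_IDS:
        raise FixtureIntegrityError("compounds: compound_id must cover 1..31 exactly")
    bad = set(df["scaffold"]) - SCAFFOLDS
    if bad:
        raise FixtureIntegrityError(f"compounds: unknown scaffold(s) {sorted(bad)}")
    for row, text in zip(df["compound_id"], df["substituents"]):
        try:
            parse_substituents(text if isinstance(text, str) else "")
        except ParseError as exc:
            raise FixtureIntegrityError(f"compounds: compound {row}: {exc}") from exc


def _validate_descriptors(df: pd.DataFrame) -> None:
    if set(df["compound_id"]) != ALL_COMPOUND_IDS:
        raise FixtureIntegrityError("descriptors: compound_id must cover 1..31 exactly")
    values = df[list(DESCRIPTOR_NAMES)].to_numpy()
    if not np.all(np.isfinite(values)):
        raise FixtureIntegrityError("descriptors: non-finite value")
    if (df["vsurf_DW23"] < 0).any():
        raise FixtureIntegrityError("descriptors: vsurf_DW23 must be nonnegative")
    if (df["vsurf_G"] < 1).any():
        raise FixtureIntegrityError("descriptors: vsurf_G must be >= 1 (surface globularity)")


def _validate_cytotoxicity(df: pd.DataFrame) -> None:
    bad = set(df["cell_line"]) - CELL_LINES
    if bad:
        raise FixtureIntegrityError(f"cytotoxicity: unknown cell line(s) {sorted(bad)}")
    for tid in df["treatment_id"]:
        if tid in CONTROL_TREATMENTS:
            continue
        if not _INT_RE.match(tid) or int(tid) not in ALL_COMPOUND_IDS:
            raise FixtureIntegrityError(f"cytotoxicity: unknown treatment_id {tid!r}")
    if (df["ic50_mean"] <= 0).any():
        raise FixtureIntegrityError("cytotoxicity: ic50_mean must be > 0")
    if (df["ic50_sd"] < 0).any():
        raise FixtureIntegrityError("cytotoxicity: ic50_sd must be >= 0")
    for line in ("KB", "KB_MDR1"):
        sub = df[df["cell_line"] == line]
        if "negative_control" not in set(sub["treatment_id"]):
            raise FixtureIntegrityError(f"cytotoxicity: missing negative control for {line}")


def _validate_reversal_printed(df: pd.DataFrame) -> None:
    if (df[["rf_mdr1", "rf_kb", "rf_cross"]].to_numpy() <= 0).any():
        raise FixtureIntegrityError("reversal_printed: folds must be positive")


def _validate_qsar_printed(df: pd.DataFrame) -> None:
    if set(df["compound_id"]) != ALL_COMPOUND_IDS:
        raise FixtureIntegrityError("qsar_printed: compound_id must cover 1..31 exactly")
    delta = df["residual"] - (df["ic50_experimental"] - df["ic50_predicted"])
    if (delta.abs() > 0.001).any():
        bad = df.loc[delta.abs() > 0.001, "compound_id"].tolist()
        raise FixtureIntegrityError(
            f"qsar_printed: residual != experimental - predicted for compounds {bad}"
        )


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        TableSchema(
            "compounds",
            columns=("compound_id", "name", "cas", "scaffold", "substituents"),
            int_columns=("compound_id",),
            key_columns=("compound_id",),
            validator=_validate_compounds,
        ),
        TableSchema(
            "descriptors",
            columns=("compound_id",) + DESCRIPTOR_NAMES,
            int_columns=("compound_id",),
            float_columns=DESCRIPTOR_NAMES,
            key_columns=("compound_id",),
            validator=_validate_descriptors,
        ),
        TableSchema(
            "cytotoxicity",
            columns=("treatment_id", "cell_line", "ic50_mean", "ic50_sd"),
            float_columns=("ic50_mean", "ic50_sd"),
            key_columns=("treatment_id", "cell_line"),
            validator=_validate_cytotoxicity,
        ),
        TableSchema(
            "reversal_printed",
            columns=("treatment_id", "rf_mdr1", "rf_kb", "rf_cross"),
            float_columns=("rf_mdr1", "rf_kb", "rf_cross"),
            key_columns=("treatment_id",),
            validator=_validate_reversal_printed,
        ),
        TableSchema(
            "qsar_printed",
            columns=("compound_id", "ic50_experimental", "ic50_predicted", "residual"),
            int_columns=("compound_id",),
            float_columns=("ic50_experimental", "ic50_predicted", "residual"),
            key_columns=("compound_id",),
            validator=_validate_qsar_printed,
        ),
    )
}

#: rows of the cytotoxicity table whose printed fold statistics are known to be
#: mutually inconsistent with the printed IC50 means (the positive-control
#: elacridar row: 3.102/0.473 = 6.558 != 6.818, while 3.102/0.455 = 6.818 —
#: the two IC50 cells appear swapped relative to the fold columns).  Stored
#: verbatim; flagged here and by `reversal.reversal_table`, never "fixed".
KNOWN_DATA_QUALITY_FLAGS = {
    "cytotoxicity": ("elacridar",),
    "reversal_printed": ("elacridar",),
}


def _parse_frame(raw: pd.DataFrame, schema: TableSchema, source: str) -> pd.DataFrame:
    missing = [c for c in schema.columns if c not in raw.columns]
    if missing:
        raise ParseError(f"{source}: missing column(s) {missing}")
    out: dict[str, list] = {}
    for col in schema.columns:
        cells = raw[col].tolist()
        if col in schema.int_columns:
            out[col] = [_parse_int(c, i + 2, col) for i, c in enumerate(cells)]
        elif col in schema.float_columns:
            out[col] = [_parse_float(c, i + 2, col) for i, c in enumerate(cells)]
        else:
            out[col] = [c.strip() for c in cells]
    df = pd.DataFrame(out, columns=list(schema.columns))
    if schema.key_columns:
        dup = df.duplicated(subset=list(schema.key_columns))
        if dup.any():
            keys = df.loc[dup, list(schema.key_columns)].to_records(index=False).tolist()
            raise ParseError(f"{source}: duplicate key(s) {keys}")
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Parameters
    ----------
    path:
        CSV file with a header row, comma separator and ``.`` decimals.
    schema:
        One of ``compounds``, ``descriptors``, ``cytotoxicity``,
        ``reversal_printed``, ``qsar_printed``.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    df = _parse_frame(raw, sch, source=str(path))
    if sch.validator is not None:
        sch.validator(df)
    df.attrs["schema"] = schema
    df.attrs["data_quality_flags"] = list(KNOWN_DATA_QUALITY_FLAGS.get(schema, ()))
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a table as UTF-8 CSV (comma separator, ``.`` decimals, header)."""
    schema = schema or df.attrs.get("schema")
    if schema is not None and schema in SCHEMAS:
        cols = [c for c in SCHEMAS[schema].columns if c in df.columns]
        df = df[cols + [c for c in df.columns if c not in cols]]
    df.to_csv(path, index=False, encoding="utf-8")


def load_fixture(table_name: str) -> pd.DataFrame:
    """Load one of the packaged study tables, validated against its schema.

    ``compounds``, ``cytotoxicity`` and ``descriptors`` are the primary
    inputs; ``reversal_printed`` and ``qsar_printed`` carry the originally
    reported fold statistics and model predictions used for concordance
    checks.
    """
    if table_name not in SCHEMAS:
        raise ValueError(f"unknown fixture {table_name!r}; choose from {sorted(SCHEMAS)}")
    ref = resources.files("flavopgp").joinpath(f"fixtures/{table_name}.csv")
    with resources.as_file(ref) as path:
        try:
            return read_table(path, table_name)
        except ParseError as exc:
            raise FixtureIntegrityError(f"fixture {table_name}: {exc}") from exc


def response_table(cytotoxicity: pd.DataFrame | None = None) -> pd.DataFrame:
    """Dependent variable of the QSAR model: daunorubicin IC50 (μM) in
    KB/MDR1 cells under each flavonoid, one row per compound_id."""
    cyto = load_fixture("cytotoxicity") if cytotoxicity is None else cytotoxicity
    rows = cyto[(cyto["cell_line"] == "KB_MDR1")
                & (~cyto["treatment_id"].isin(CONTROL_TREATMENTS))]
    out = pd.DataFrame(
        {
            "compound_id": rows["treatment_id"].astype(int).to_numpy(),
            "ic50": rows["ic50_mean"].to_numpy(),
        }
    ).sort_values("compound_id", ignore_index=True)
    return out


# --------------------------------------------------------------------------
# train/test split

@dataclass(frozen=True)
class SplitSpec:
    """Fixed partition of the 31 compounds into training and external test sets.

    The default reserves compounds {2, 4, 9, 20, 22, 27, 30} as the external
    test set, leaving 24 compounds for training.
    """

    test_ids: frozenset[int]
    train_ids: frozenset[int]

    def __post_init__(self) -> None:
        if self.test_ids & self.train_ids:
            raise ConsistencyError("split: test and train ids overlap")

    @classmethod
    def default(cls) -> "SplitSpec":
        return cls.from_test_ids(DEFAULT_TEST_IDS)

    @classmethod
    def from_test_ids(
        cls, test_ids: Iterable[int], all_ids: Iterable[int] = ALL_COMPOUND_IDS
    ) -> "SplitSpec":
        test = frozenset(int(i) for i in test_ids)
        universe = frozenset(int(i) for i in all_ids)
        extra = test - universe
        if extra:
            raise ConsistencyError(f"split: test ids {sorted(extra)} outside compound set")
        return cls(test_ids=test, train_ids=universe - test)

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls.from_test_ids(payload["test_ids"])


def default_split() -> SplitSpec:
    return SplitSpec.default()


@dataclass(frozen=True)
class TrainTestTables:
    train_descriptors: pd.DataFrame
    train_response: pd.DataFrame
    test_descriptors: pd.DataFrame
    test_response: pd.DataFrame


def split_train_test(
    descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    spec: SplitSpec | None = None,
) -> TrainTestTables:
    """Partition descriptor and response tables according to a split spec.

    Every id named by the spec must be present in both tables; row order is
    preserved within each partition.
    """
    spec = spec or SplitSpec.default()
    for name, table in (("descriptors", descriptors), ("responses", responses)):
        present = set(table["compound_id"])
        missing = (spec.test_ids | spec.train_ids) - present
        if missing:
            raise ConsistencyError(f"split: ids {sorted(missing)} absent from {name} table")
    d_tr = descriptors[descriptors["compound_id"].isin(spec.train_ids)].reset_index(drop=True)
    d_te = descriptors[descriptors["compound_id"].isin(spec.test_ids)].reset_index(drop=True)
    r_tr = responses[responses["compound_id"].isin(spec.train_ids)].reset_index(drop=True)
    r_te = responses[responses["compound_id"].isin(spec.test_ids)].reset_index(drop=True)
    return TrainTestTables(d_tr, r_tr, d_te, r_te)
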