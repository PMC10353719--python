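"""Table input, validation, z-score normalization, and result output.

The analysis operates on a rectangular numeric table with one header row of
feature names and a first column of sample identifiers (rows = samples,
columns = features).  Missing values are a hard error: the method requires
fully imputed input, and every offending cell is named so the user can fix
the upstream imputation rather than guess.  Constant features are flagged —
their distance variance is zero, which makes distance correlation undefined —
and excluded from pairwise computation instead of being silently zero-filled.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SidcorError(ValueError):
    """Base class for all user-facing errors raised by this package."""


class TableFormatError(SidcorError):
    """The input file is not a rectangular numeric table."""


class MissingValueError(SidcorError):
    """The table contains missing cells (input must be pre-imputed)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawTable:
    """Unprocessed user input: possibly-missing numeric grid with labels.

    ``values`` is an ``(n_samples, n_features)`` float array in which missing
    cells are NaN.  Validation (completeness, constant-column detection)
    happens in :func:`validate`; parsing only guarantees shape and numeric
    content of the non-empty cells.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n, m = vals.shape
        if n < 3:
            raise TableFormatError(
                f"need at least 3 samples (rows), got {n}: the t-based p-value "
                "requires n-2 >= 1 degrees of freedom"
            )
        if m < 2:
            raise TableFormatError(
                f"need at least 2 features (columns), got {m}"
            )
        dupes = _duplicates(self.feature_names)
        if dupes:
            raise TableFormatError(
                "duplicate feature names in header: " + ", ".join(sorted(dupes))
            )
        if any(not name for name in self.feature_names):
            raise TableFormatError("empty feature name in header")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Validated, fully observed samples x features matrix.

    ``constant_features`` holds the names of columns whose pre-normalization
    variance is exactly zero.  Those columns are retained in ``values`` (and
    left untouched by :func:`zscore`) but must be excluded from any
    correlation computation.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    constant_features: frozenset[str] = field(default_factory=frozenset)
    normalized: bool = False

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def usable_indices(self) -> np.ndarray:
        """Indices of non-constant features, in original column order."""
        return np.array(
            [i for i, f in enumerate(self.feature_names)
             if f not in self.constant_features],
            dtype=int,
        )

    @property
    def usable_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.feature_names
                     if f not in self.constant_features)

    def column(self, feature: str | int) -> np.ndarray:
        if isinstance(feature, str):
            feature = self.feature_names.index(feature)
        return self.values[:, feature]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _duplicates(names: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for n in names:
        if n in seen:
            dup.add(n)
        seen.add(n)
    return dup


def _cell_to_float(cell, row_label: str, col_label: str) -> float:
    """Parse one cell; empty -> NaN, non-numeric -> TableFormatError."""
    if cell is None:
        return math.nan
    if isinstance(cell, (int, float)):
        return float(cell)
    text = str(cell).strip()
    if text == "" or text.lower() in ("nan", "na"):
        return math.nan
    try:
        return float(text)  # dot decimal separator, locale-independent
    except ValueError:
        raise TableFormatError(
            f"non-numeric cell at sample '{row_label}', feature "
            f"'{col_label}': {text!r}"
        ) from None


def _table_from_rows(rows: list[list], source: str) -> RawTable:
    if not rows:
        raise TableFormatError(f"{source}: file is empty")
    header = ["" if c is None else str(c).strip() for c in rows[0]]
    if len(header) < 3:
        raise TableFormatError(
            f"{source}: header must contain an ID column plus at least 2 features"
        )
    feature_names = tuple(header[1:])
    width = len(header)
    sample_ids: list[str] = []
    grid: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        # openpyxl can return short rows; pad trailing Nones, but a row that
        # is longer than the header is structurally broken.
        if len(row) > width:
            raise TableFormatError(
                f"{source}: row {r} has {len(row)} fields, header has {width} "
                "(table is not rectangular)"
            )
        row = list(row) + [None] * (width - len(row))
        sid = "" if row[0] is None else str(row[0]).strip()
        sample_ids.append(sid)
        grid.append([
            _cell_to_float(row[j], sid, feature_names[j - 1])
            for j in range(1, width)
        ])
    return RawTable(tuple(sample_ids), feature_names, np.array(grid, dtype=float))


def read_table(path: str | Path, dialect: str | None = None) -> RawTable:
    """Read a CSV or XLSX table (header row + ID column) into a RawTable.

    ``dialect`` is ``"csv"`` or ``"xlsx"``; when omitted it is inferred from
    the file suffix.  CSV parsing follows RFC 4180 with a dot decimal
    separator; XLSX uses the first sheet.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"input file does not exist: {path}")
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8-sig") as fh:
            rows = [row for row in csv.reader(fh)]
        # csv.reader is ragged-tolerant; enforce rectangularity here so the
        # error can name the offending row.
        if rows:
            width = len(rows[0])
            for r, row in enumerate(rows, start=1):
                if len(row) != width:
                    raise TableFormatError(
                        f"{path.name}: row {r} has {len(row)} fields, expected "
                        f"{width} (table is not rectangular)"
                    )
    elif dialect == "xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        rows = [list(row) for row in ws.iter_rows(values_only=True)]
        wb.close()
    else:
        raise SidcorError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")
    return _table_from_rows(rows, path.name)


def transpose(raw: RawTable) -> RawTable:
    """Swap the sample/feature orientation of a parsed table."""
    return RawTable(raw.feature_names, raw.sample_ids, raw.values.T)


# ---------------------------------------------------------------------------
# Validation and normalization
# ---------------------------------------------------------------------------

def validate(raw: RawTable) -> FeatureMatrix:
    """Check completeness and flag constant columns.

    Raises :class:`MissingValueError` naming *every* (sample, feature)
    coordinate with a missing value — the method requires pre-imputed input
    and never imputes silently.
    """
    missing = np.argwhere(np.isnan(raw.values))
    if missing.size:
        coords = ", ".join(
            f"(sample '{raw.sample_ids[i]}', feature '{raw.feature_names[j]}')"
            for i, j in missing
        )
        raise MissingValueError(
            f"missing values must be imputed before analysis; "
            f"{len(missing)} missing cell(s) found at: {coords}"
        )
    constant = frozenset(
        raw.feature_names[j]
        for j in range(raw.n_features)
        if np.all(raw.values[:, j] == raw.values[0, j])
    )
    return FeatureMatrix(
        raw.sample_ids, raw.feature_names, raw.values.copy(),
        constant_features=constant, normalized=False,
    )


def zscore(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each non-constant column: (x - mean) / sd, sample sd (ddof=1).

    Constant columns are left untouched (they stay flagged and excluded
    downstream).  Idempotent up to floating-point roundoff.
    """
    values = fm.values.copy()
    for j, name in enumerate(fm.feature_names):
        if name in fm.constant_features:
            continue
        col = values[:, j]
        values[:, j] = (col - col.mean()) / col.std(ddof=1)
    return replace(fm, values=values, normalized=True)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

#: Result-table columns, in the fixed output order, per analysis mode.
EDGE_COLUMNS = {
    "one_to_one": ["feature_a", "feature_b", "dcor", "sign", "signed_dcor",
                   "p_dcor", "pearson_r", "p_pearson", "spearman_rho",
                   "p_spearman", "mode"],
    "one_to_all": ["feature_a", "feature_b", "dcor", "sign", "signed_dcor",
                   "p_dcor", "pearson_r", "p_pearson", "spearman_rho",
                   "p_spearman", "n_covariates", "mode"],
    "partial": ["feature_a", "feature_b", "partial_rho", "z", "p_partial",
                "mode"],
}

XLSX_SHEET_NAME = "sidco_results"


def write_results(edges: pd.DataFrame, path: str | Path,
                  dialect: str | None = None) -> Path:
    """Serialize an edge table to CSV or XLSX at full double precision.

    Column order is preserved as given (callers build tables with the fixed
    EDGE_COLUMNS order); an empty table yields a header-only file.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    try:
        if dialect == "csv":
            edges.to_csv(path, index=False, lineterminator="\n")
        elif dialect == "xlsx":
            edges.to_excel(path, sheet_name=XLSX_SHEET_NAME, index=False)
        else:
            raise SidcorError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")
    except OSError as exc:
        raise SidcorError(f"cannot write results to {path}: {exc}") from exc
    return path


def write_raw_table(raw: RawTable, path: str | Path,
                    dialect: str | None = None) -> Path:
    """Write a RawTable back to disk (used by the fixture generator)."""
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() == ".xlsx" else "csv"
    df = pd.DataFrame(raw.values, columns=list(raw.feature_names))
    df.insert(0, "sample_id", list(raw.sample_ids))
    try:
        if dialect == "csv":
            df.to_csv(path, index=False, lineterminator="\n")
        elif dialect == "xlsx":
            df.to_excel(path, sheet_name="data", index=False)
        else:
            raise SidcorError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")
    except OSError as exc:
        raise SidcorError(f"cannot write table to {path}: {exc}") from exc
    return path
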