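"""Shared data model and tabular I/O.

All interchange formats are plain text: expression matrices and metabolite
tables are tab-separated with a ``gene_id`` / ``metabolite_id`` key column
and one column per sample; sample annotations live in a separate sample
sheet (``sample_id, condition, time_h, replicate``); gene sets use the
standard GMT dialect. Values are FPKM-scale (dimensionless, non-negative);
time is in hours. Missing values are an error, never imputed — the AUC
summary downstream is undefined on gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "ValidationError",
    "CrossReferenceError",
    "TimeCourseExperiment",
    "GeneSet",
    "GeneSetCollection",
    "MetaboliteTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_metabolites",
    "write_results_table",
]

# Fixed float formatting keeps repeated writes byte-identical.
FLOAT_FORMAT = "%.10g"

SHEET_COLUMNS = ("sample_id", "condition", "time_h", "replicate")


class TableFormatError(ValueError):
    """A text table does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A table parses but violates a data-model invariant."""


class CrossReferenceError(ValidationError):
    """Matrix columns and sample-sheet rows do not match one-to-one."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeCourseExperiment:
    """Expression values indexed by gene x (condition, time, replicate).

    Parameters
    ----------
    values
        Genes x samples matrix; index holds unique gene identifiers,
        columns hold sample identifiers. Entries are FPKM-scale, >= 0.
    samples
        One row per sample with columns ``sample_id, condition, time_h,
        replicate``; every matrix column appears exactly once.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        # canonical dtypes so round-tripping through text is an identity
        self.samples["time_h"] = self.samples["time_h"].astype(float)
        self.samples["replicate"] = self.samples["replicate"].astype(int)
        self.values = self.values.astype(float)
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_id: {', '.join(map(str, dup))}")
        missing = [c for c in SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {missing}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample_id: {', '.join(dup)}")
        sheet_ids = set(self.samples["sample_id"])
        matrix_ids = set(self.values.columns)
        if sheet_ids != matrix_ids:
            only_matrix = sorted(matrix_ids - sheet_ids)
            only_sheet = sorted(sheet_ids - matrix_ids)
            raise CrossReferenceError(
                "matrix/sheet sample mismatch: "
                f"only in matrix {only_matrix}, only in sheet {only_sheet}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression at gene {idx[r]!r}, sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {idx[r]!r}, sample {self.values.columns[c]!r}"
            )
        bad_t = self.samples["time_h"] < 0
        if bad_t.any():
            raise ValidationError(
                f"negative time_h for sample {self.samples.loc[bad_t, 'sample_id'].iloc[0]!r}"
            )
        if (self.samples["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        for cond, sub in self.samples.groupby("condition", sort=False):
            grids = {
                rep: tuple(sorted(g["time_h"]))
                for rep, g in sub.groupby("replicate", sort=False)
            }
            ref = next(iter(grids.values()))
            for rep, grid in grids.items():
                if grid != ref:
                    raise ValidationError(
                        f"condition {cond!r}: replicate {rep} time grid {grid} "
                        f"differs from {ref}"
                    )
                if len(set(grid)) != len(grid):
                    raise ValidationError(
                        f"condition {cond!r}, replicate {rep}: duplicate time points"
                    )
            if 0 not in ref:
                raise ValidationError(f"condition {cond!r}: time 0 missing")
            if len(ref) < 2:
                raise ValidationError(
                    f"condition {cond!r}: needs >= 2 distinct time points"
                )

    # -- accessors ----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def time_grid(self, condition: str) -> np.ndarray:
        sub = self.samples[self.samples["condition"] == condition]
        if sub.empty:
            raise KeyError(
                f"unknown condition {condition!r}; available: {self.conditions}"
            )
        return np.array(sorted(sub["time_h"].unique()), dtype=float)

    def equals(self, other: "TimeCourseExperiment") -> bool:
        a = self.samples[list(SHEET_COLUMNS)].reset_index(drop=True)
        b = other.samples[list(SHEET_COLUMNS)].reset_index(drop=True)
        return self.values.equals(other.values) and a.equals(b)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        self.members = list(dict.fromkeys(self.members))  # de-duplicate, keep order
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValidationError(f"duplicate gene set names: {sorted(dup)}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def same_membership(self, other: "GeneSetCollection") -> bool:
        if self.names != other.names:
            return False
        return all(
            set(a.members) == set(b.members) for a, b in zip(self.sets, other.sets)
        )


@dataclass
class MetaboliteTable:
    """Metabolite x sample abundances with a group label per sample.

    Abundances are internal-standard-normalized (dimensionless, >= 0).
    """

    values: pd.DataFrame
    groups: pd.Series  # sample_id -> group label

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metabolite_id: {dup}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise CrossReferenceError(f"samples without group label: {missing}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("abundances must be finite and >= 0")

    def group_samples(self, group: str) -> list[str]:
        ids = list(self.groups.index[self.groups == group])
        if not ids:
            raise KeyError(
                f"unknown group {group!r}; available: "
                f"{list(dict.fromkeys(self.groups))}"
            )
        return ids


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path: str | Path, key: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != key:
        raise TableFormatError(
            f"{path}: first column must be {key!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(key)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise TableFormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at "
                f"{key}={bad.index[0]!r}, column {col!r}"
            ) from exc
        if df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise ValidationError(
                f"{path}: missing value at {key}={row!r}, column {col!r}"
            )
    return df


def _read_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise TableFormatError(f"{path}: sample sheet lacks columns {missing}")
    sheet["time_h"] = pd.to_numeric(sheet["time_h"])
    sheet["replicate"] = pd.to_numeric(sheet["replicate"], downcast="integer")
    return sheet[list(SHEET_COLUMNS)]


def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> TimeCourseExperiment:
    """Read an expression matrix TSV plus its sample sheet and validate.

    Raises
    ------
    TableFormatError
        Wrong header or non-numeric cell (named by row/column).
    ValidationError
        Duplicate genes, negative values, or a malformed time grid.
    CrossReferenceError
        Samples present in only one of the two files.
    """
    values = _read_matrix(matrix_path, "gene_id")
    sheet = _read_sheet(sheet_path)
    return TimeCourseExperiment(values=values, samples=sheet)


def write_expression(
    exp: TimeCourseExperiment, matrix_path: str | Path, sheet_path: str | Path
) -> None:
    exp.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")
    exp.samples.to_csv(sheet_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_metabolites(table_path: str | Path, sheet_path: str | Path) -> MetaboliteTable:
    """Read a metabolite abundance TSV; the shared sample sheet's
    ``condition`` column is reused as the group label."""
    values = _read_matrix(table_path, "metabolite_id")
    sheet = _read_sheet(sheet_path)
    groups = sheet.set_index("sample_id")["condition"]
    common = [c for c in values.columns if c in groups.index]
    if set(values.columns) - set(common):
        raise CrossReferenceError(
            f"samples absent from sheet: {sorted(set(values.columns) - set(common))}"
        )
    return MetaboliteTable(values=values, groups=groups.loc[list(values.columns)])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB members...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}: line {lineno}: GMT record needs >= 3 fields, got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], fields[2:]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def write_results_table(
    records: Sequence[Mapping] | pd.DataFrame, path: str | Path
) -> None:
    """Write per-gene or per-set records as a deterministic TSV.

    Rows are sorted by the first (primary-key) column; an empty record
    list still produces a header-only file when a DataFrame with columns
    is given.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if len(df.columns):
        df = df.sort_values(df.columns[0], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
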