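"""Domain types for matrix chains.

A chain links tables that do not share a single common index: the columns of
each matrix are indexed over the same identifier set as the rows of the next,
so a labeling of one matrix's columns can be transferred to the next matrix's
rows.  The types here are deliberately thin wrappers around pandas DataFrames:
they add identifier-uniqueness and value-domain validation, the chain
compatibility check, and a TSV round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALUE_KINDS = ("continuous", "binary", "categorical")


class MatrixError(ValueError):
    """Raised when a matrix violates a structural invariant."""


class ChainError(ValueError):
    """Raised when consecutive matrices cannot be chained."""


def _check_unique(ids: Sequence, axis: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise MatrixError(f"duplicate {axis} identifier: {i!r}")
        seen.add(i)


@dataclass
class IndexedMatrix:
    """A rectangular table with unique row and column identifiers.

    Parameters
    ----------
    data
        DataFrame whose index holds row identifiers and whose columns hold
        column identifiers.  For ``continuous`` and ``binary`` kinds the
        values are floats with NaN marking missing entries; for
        ``categorical`` each cell is a frozenset of category strings (the
        empty set marks an absent/missing annotation).
    value_kind
        One of ``continuous``, ``binary``, ``categorical``.
    """

    data: pd.DataFrame
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise MatrixError(f"unknown value_kind {self.value_kind!r}")
        _check_unique(list(self.data.index), "row")
        _check_unique(list(self.data.columns), "column")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.value_kind == "categorical":
            self.data = self.data.map(_as_category_set)
        else:
            try:
                self.data = self.data.astype(float)
            except (TypeError, ValueError) as exc:
                raise MatrixError(f"non-numeric cell in {self.value_kind} matrix: {exc}") from exc
            vals = self.data.to_numpy()
            if np.isinf(vals).any():
                r, c = np.argwhere(np.isinf(vals))[0]
                raise MatrixError(
                    f"non-finite value at ({self.data.index[r]!r}, {self.data.columns[c]!r})"
                )
            if self.value_kind == "binary":
                bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
                if bad.any():
                    r, c = np.argwhere(bad)[0]
                    raise MatrixError(
                        "binary matrix holds value "
                        f"{vals[r, c]!r} at ({self.data.index[r]!r}, {self.data.columns[c]!r})"
                    )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def transpose(self) -> "IndexedMatrix":
        return IndexedMatrix(self.data.T.copy(), self.value_kind)

    def reorder_rows(self, row_ids: Sequence[str]) -> "IndexedMatrix":
        return IndexedMatrix(self.data.loc[list(row_ids)].copy(), self.value_kind)


def _as_category_set(cell) -> frozenset:
    if isinstance(cell, frozenset):
        return cell
    if isinstance(cell, (set, list, tuple)):
        return frozenset(str(c) for c in cell)
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    s = str(cell).strip()
    if not s:
        return frozenset()
    return frozenset(part.strip() for part in s.split(",") if part.strip())


def read_matrix(path: str | Path, value_kind: str = "continuous") -> IndexedMatrix:
    """Read a TSV matrix: header row of column ids, first field the row id.

    Empty fields denote missing entries.  Categorical cells may hold a
    comma-separated set of categories.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "row")
    _check_unique(list(df.columns), "column")
    if value_kind == "categorical":
        return IndexedMatrix(df.map(_as_category_set), value_kind)

    def parse(cell: str, r, c) -> float:
        if cell.strip() == "" or cell.strip().upper() in ("NA", "NAN"):
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise MatrixError(f"non-numeric cell {cell!r} at ({r!r}, {c!r})") from None

    out = pd.DataFrame(
        [[parse(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
         for i in range(df.shape[0])],
        index=df.index,
        columns=df.columns,
    )
    return IndexedMatrix(out, value_kind)


def write_matrix(matrix: IndexedMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing entries become empty fields."""
    if matrix.value_kind == "categorical":
        df = matrix.data.map(lambda s: ",".join(sorted(s)))
        df.to_csv(path, sep="\t")
    else:
        matrix.data.to_csv(path, sep="\t", na_rep="")


@dataclass
class MatrixChain:
    """Ordered matrices where each matrix's columns index the next's rows."""

    matrices: list[IndexedMatrix]

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, k: int) -> IndexedMatrix:
        return self.matrices[k]


def build_chain(matrices: Sequence[IndexedMatrix]) -> MatrixChain:
    """Validate chain compatibility and canonicalise row orders.

    Consecutive matrices must satisfy ``set(cols of k) == set(rows of k+1)``;
    matrix ``k+1`` is reordered so its rows follow matrix ``k``'s column
    order, making positional label transfer valid.  Orientation (which axis
    is which) is the caller's responsibility.
    """
    if len(matrices) < 2:
        raise ChainError("a chain needs at least two matrices")
    out = [matrices[0]]
    for k in range(len(matrices) - 1):
        cols = set(out[k].col_ids)
        rows = set(matrices[k + 1].row_ids)
        if cols != rows:
            diff = sorted(cols.symmetric_difference(rows))
            shown = ", ".join(map(repr, diff[:10]))
            raise ChainError(
                f"matrices {k} and {k + 1} are index-incompatible; "
                f"symmetric difference ({len(diff)} ids): {shown}"
            )
        out.append(matrices[k + 1].reorder_rows(out[k].col_ids))
    return MatrixChain(out)


@dataclass
class Labeling:
    """Assignment of each identifier of one index set to a small label set.

    ``assignments`` maps identifier -> label; identifiers mapped to ``None``
    are explicitly unlabeled (untestable downstream).  ``label_set`` fixes
    the order of the admitted labels; the first entry is the group whose
    statistics are reported first by discriminators.
    """

    index_set_id: str
    assignments: dict[str, str | None]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {l for l in self.assignments.values() if l is not None and l not in self.label_set}
        if bad:
            raise ValueError(f"labels outside label_set: {sorted(bad)}")

    def ids_with(self, label: str) -> list[str]:
        return [i for i, l in self.assignments.items() if l == label]

    def labeled_ids(self) -> list[str]:
        return [i for i, l in self.assignments.items() if l is not None]

    def present_labels(self) -> list[str]:
        present = {l for l in self.assignments.values() if l is not None}
        return [l for l in self.label_set if l in present]


@dataclass
class StepResult:
    """Per-column statistics of one discriminator pass.

    ``table`` is indexed by column identifier with columns
    ``n_hi, n_lo, mean_hi, mean_lo, score, sensitivity_score, p_value,
    q_value, label, testable, reason``, where hi/lo refer to the first and
    second label of the slicing labeling.
    """

    step_index: int
    group_labels: tuple[str, str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        testable = self.table["testable"].astype(bool)
        for col in ("p_value", "q_value"):
            v = self.table.loc[testable, col].to_numpy(dtype=float)
            if v.size and ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} outside [0, 1] in step {self.step_index}")


@dataclass
class CrossPattern:
    """A source-feature -> final-feature link supported through the chain."""

    source_feature: str
    target_feature: str
    label_path: tuple[str, ...]
    final_p: float
    final_q: float
    tier: int | None
    step_stats: list[pd.Series] = field(default_factory=list)
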