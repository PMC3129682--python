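"""Labelers and discriminators.

A *labeler* turns a vector of feature values into a two-class labeling of an
index set (hi/lo by median split, or directly from a 0/1 feature).  A
*discriminator* takes a matrix whose rows carry a transferred labeling,
slices the rows by label, tests each column for a difference between the
slices, applies multiple-testing correction across that step's testable
columns, and emits a new labeling of the columns (sensitive/insensitive).

Two discriminators are provided: a continuous one built on Welch's unequal
variance t-test and a binary one built on the hypergeometric upper tail.
Alongside Welch's t the continuous discriminator records a descriptive
*sensitivity score* — the mean difference divided by the difference of the
two groups' standard errors.  That denominator can vanish or change sign, so
the score is reported for inspection only; inference always uses Welch's t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import IndexedMatrix, Labeling, MatrixError, StepResult

DISCRIMINATOR_KINDS = ("welch", "hypergeometric", "categorical")


class DegenerateSplitWarning(UserWarning):
    """Emitted when a labeler cannot form two classes."""


class UntestableColumn(Exception):
    """A column cannot be tested; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class DiscriminatorConfig:
    """Parameters of one discriminator step.

    alpha is the per-step significance threshold applied to q-values when
    ``correction='bh_fdr'`` (the default) or to raw p-values when
    ``correction='none'``.  ``min_group_size`` is the smallest slice size a
    column may be tested with; 3 guarantees a defined Welch df.
    """

    kind: str = "welch"
    alpha: float = 0.05
    correction: str = "bh_fdr"
    min_group_size: int = 3
    sensitive_label: str = "sensitive"
    insensitive_label: str = "insensitive"

    def __post_init__(self) -> None:
        if self.kind not in DISCRIMINATOR_KINDS:
            raise ValueError(f"unknown discriminator kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bh_fdr", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")


# ---------------------------------------------------------------------------
# labelers

def median_split_label(
    values: Mapping[str, float],
    index_set_id: str = "",
    hi_label: str = "hi",
    lo_label: str = "lo",
) -> Labeling:
    """Label identifiers ``hi`` if strictly above the median, else ``lo``.

    The median is computed over non-missing values (even count: mean of the
    central pair); ties at the median go ``lo``.  Missing-valued identifiers
    stay unlabeled.
    """
    clean = {k: float(v) for k, v in values.items() if v is not None and np.isfinite(v)}
    if len(clean) < 2:
        raise ValueError("median split needs at least 2 non-missing values")
    med = float(np.median(list(clean.values())))
    assignments: dict[str, str | None] = {}
    for k, v in values.items():
        if k in clean:
            assignments[k] = hi_label if clean[k] > med else lo_label
        else:
            assignments[k] = None
    if hi_label not in assignments.values():
        warnings.warn(
            "degenerate median split: no value strictly above the median; "
            "all identifiers labeled " + repr(lo_label),
            DegenerateSplitWarning,
            stacklevel=2,
        )
    return Labeling(index_set_id, assignments, (hi_label, lo_label))


def binary_label(
    values: Mapping[str, float],
    one_label: str,
    zero_label: str,
    index_set_id: str = "",
) -> Labeling:
    """Label identifiers by a 0/1 feature: 1 -> one_label, 0 -> zero_label."""
    assignments: dict[str, str | None] = {}
    for k, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            assignments[k] = None
        elif v == 1:
            assignments[k] = one_label
        elif v == 0:
            assignments[k] = zero_label
        else:
            raise ValueError(f"non-binary value {v!r} for identifier {k!r}")
    present = {l for l in assignments.values() if l is not None}
    if len(present) < 2:
        warnings.warn(
            "single-class binary labeling; downstream slicing will produce an empty slice",
            DegenerateSplitWarning,
            stacklevel=2,
        )
    return Labeling(index_set_id, assignments, (one_label, zero_label))


def slice_rows(matrix: IndexedMatrix, labeling: Labeling) -> dict[str, IndexedMatrix]:
    """Partition a matrix's rows by label; unlabeled rows appear in no slice."""
    missing = [i for i in labeling.assignments if i not in set(matrix.row_ids)]
    if missing:
        raise ValueError(f"labeling refers to rows absent from the matrix: {missing[:10]}")
    out = {}
    for label in labeling.label_set:
        keep = [i for i in matrix.row_ids if labeling.assignments.get(i) == label]
        out[label] = IndexedMatrix(matrix.data.loc[keep].copy(), matrix.value_kind)
    return out


# ---------------------------------------------------------------------------
# elementary statistics

class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny) with sample variances;
    degrees of freedom by Welch–Satterthwaite.  Both variances zero with
    equal means yields (t=0, p=1); zero variances with unequal means raises
    :class:`UntestableColumn` ("degenerate variance").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise UntestableColumn("min_group_size")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return WelchResult(0.0, float(nx + ny - 2), 1.0)
        raise UntestableColumn("degenerate variance")
    a, b = vx / nx, vy / ny
    t = (mx - my) / math.sqrt(a + b)
    df = (a + b) ** 2 / (a * a / (nx - 1) + b * b / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def sensitivity_score(x_hi, x_lo) -> float:
    """Mean difference over the *difference* of the standard errors.

    A descriptive statistic only: the denominator se(hi) - se(lo) can be
    zero (score undefined, returned as NaN) or negative; p-values always
    come from :func:`welch_t`.
    """
    x_hi = np.asarray(x_hi, dtype=float)
    x_lo = np.asarray(x_lo, dtype=float)
    x_hi = x_hi[~np.isnan(x_hi)]
    x_lo = x_lo[~np.isnan(x_lo)]
    if len(x_hi) < 2 or len(x_lo) < 2:
        return float("nan")
    se_hi = x_hi.std(ddof=1) / math.sqrt(len(x_hi))
    se_lo = x_lo.std(ddof=1) / math.sqrt(len(x_lo))
    denom = se_hi - se_lo
    if denom == 0.0:
        return float("nan")
    return float((x_hi.mean() - x_lo.mean()) / denom)


def hypergeom_tail(x: int, m: int, n: int, k: int) -> float:
    """Upper tail P(X >= x): probability of drawing at least ``x`` white
    balls from an urn of ``m`` white and ``n`` black when ``k`` are drawn.
    """
    if not (0 <= k <= m + n):
        raise ValueError("require 0 <= k <= m + n")
    if x > min(m, k):
        return 0.0
    if x <= max(0, k - n):
        return 1.0
    return float(stats.hypergeom.sf(x - 1, m + n, m, k))


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# discriminators

def _vector_welch(A: np.ndarray, B: np.ndarray, min_n: int):
    """Column-wise Welch test over two row-slices with NaN-aware reduction.

    Returns (n_a, n_b, mean_a, mean_b, t, p, testable, reason) arrays; the
    same contract as looping :func:`welch_t` per column.
    """
    na = (~np.isnan(A)).sum(axis=0)
    nb = (~np.isnan(B)).sum(axis=0)
    p_cols = A.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        ma = np.nanmean(A, axis=0)
        mb = np.nanmean(B, axis=0)
        va = np.nanvar(A, axis=0, ddof=1)
        vb = np.nanvar(B, axis=0, ddof=1)
    t = np.full(p_cols, np.nan)
    p = np.full(p_cols, np.nan)
    testable = np.ones(p_cols, dtype=bool)
    reason = np.full(p_cols, "", dtype=object)

    small = (na < min_n) | (nb < min_n)
    testable[small] = False
    reason[small] = "min_group_size"

    ok = ~small
    both_zero = ok & (va == 0) & (vb == 0)
    flat = both_zero & (ma == mb)
    t[flat], p[flat] = 0.0, 1.0
    degen = both_zero & (ma != mb)
    testable[degen] = False
    reason[degen] = "degenerate variance"

    live = ok & ~both_zero
    if live.any():
        a = va[live] / na[live]
        b = vb[live] / nb[live]
        tt = (ma[live] - mb[live]) / np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (na[live] - 1) + b**2 / (nb[live] - 1))
        t[live] = tt
        p[live] = np.minimum(2.0 * stats.t.sf(np.abs(tt), df), 1.0)
    return na, nb, ma, mb, t, p, testable, reason


def _finalize_step(
    table: pd.DataFrame, cfg: DiscriminatorConfig, step_index: int, group_labels
) -> tuple[StepResult, Labeling]:
    """Correct p-values across this step's testable columns and label them."""
    testable = table["testable"].to_numpy(dtype=bool)
    q = np.full(len(table), np.nan)
    if testable.any():
        p = table.loc[testable, "p_value"].to_numpy(dtype=float)
        q[testable] = bh_fdr(p) if cfg.correction == "bh_fdr" else p
    table["q_value"] = q
    crit = np.where(testable, q < cfg.alpha, False)
    table["label"] = np.where(crit, cfg.sensitive_label, cfg.insensitive_label)
    result = StepResult(step_index, tuple(group_labels), table)
    labeling = Labeling(
        f"step{step_index}_columns",
        dict(zip(table.index, table["label"])),
        (cfg.sensitive_label, cfg.insensitive_label),
    )
    return result, labeling


def _two_slices(matrix: IndexedMatrix, labeling: Labeling):
    if len(labeling.label_set) != 2:
        raise ValueError("discriminators require a two-label labeling")
    la, lb = labeling.label_set
    slices = slice_rows(matrix, labeling)
    return slices[la].data.to_numpy(dtype=float), slices[lb].data.to_numpy(dtype=float), (la, lb)


def discriminate_continuous(
    matrix: IndexedMatrix,
    labeling: Labeling,
    cfg: DiscriminatorConfig | None = None,
    step_index: int = 1,
) -> tuple[StepResult, Labeling]:
    """Welch-test each column between the two row-slices; label by q < alpha.

    Columns whose slices fall below ``cfg.min_group_size`` (after dropping
    missing entries column-wise) are untestable: excluded from correction and
    labeled insensitive with ``testable=False`` and a reason.
    """
    cfg = cfg or DiscriminatorConfig(kind="welch")
    A, B, (la, lb) = _two_slices(matrix, labeling)
    na, nb, ma, mb, t, p, testable, reason = _vector_welch(A, B, cfg.min_group_size)

    sens = np.full(matrix.shape[1], np.nan)
    for j in np.nonzero(testable)[0]:
        sens[j] = sensitivity_score(A[:, j], B[:, j])

    table = pd.DataFrame(
        {
            "n_hi": na, "n_lo": nb,
            "mean_hi": ma, "mean_lo": mb,
            "score": t, "sensitivity_score": sens,
            "p_value": p, "q_value": np.nan,
            "testable": testable, "reason": reason,
        },
        index=pd.Index(matrix.col_ids, name="column"),
    )
    return _finalize_step(table, cfg, step_index, (la, lb))


def discriminate_binary(
    matrix: IndexedMatrix,
    labeling: Labeling,
    cfg: DiscriminatorConfig | None = None,
    step_index: int = 1,
) -> tuple[StepResult, Labeling]:
    """Hypergeometric enrichment of 1-entries in the first-label slice.

    Per column the rows holding value 1 are the white balls, rows holding 0
    the black balls, and the rows carrying the first label the draws; the
    p-value is the inclusive upper tail P(X >= observed white draws).
    """
    if matrix.value_kind != "binary":
        raise MatrixError("discriminate_binary requires a binary matrix")
    cfg = cfg or DiscriminatorConfig(kind="hypergeometric")
    A, B, (la, lb) = _two_slices(matrix, labeling)

    cols = matrix.col_ids
    rows = {k: np.full(len(cols), np.nan) for k in ("n_hi", "n_lo", "mean_hi", "mean_lo", "score", "p_value")}
    testable = np.ones(len(cols), dtype=bool)
    reason = np.full(len(cols), "", dtype=object)
    for j in range(len(cols)):
        a = A[:, j][~np.isnan(A[:, j])]
        b = B[:, j][~np.isnan(B[:, j])]
        rows["n_hi"][j], rows["n_lo"][j] = len(a), len(b)
        if len(a) < cfg.min_group_size or len(b) < cfg.min_group_size:
            testable[j] = False
            reason[j] = "min_group_size"
            continue
        x = int(a.sum())
        m = int(a.sum() + b.sum())
        n = int(len(a) + len(b) - m)
        k = len(a)
        rows["mean_hi"][j] = a.mean()
        rows["mean_lo"][j] = b.mean()
        rows["score"][j] = x
        rows["p_value"][j] = hypergeom_tail(x, m, n, k)

    table = pd.DataFrame(
        {
            "n_hi": rows["n_hi"], "n_lo": rows["n_lo"],
            "mean_hi": rows["mean_hi"], "mean_lo": rows["mean_lo"],
            "score": rows["score"], "sensitivity_score": np.nan,
            "p_value": rows["p_value"], "q_value": np.nan,
            "testable": testable, "reason": reason,
        },
        index=pd.Index(cols, name="column"),
    )
    return _finalize_step(table, cfg, step_index, (la, lb))


def expand_categorical(matrix: IndexedMatrix) -> IndexedMatrix:
    """One binary column per observed category per original column.

    Derived columns are named ``origcol=category`` in sorted category order;
    a row whose cell is the empty set is zero across that column's derived
    features.
    """
    if matrix.value_kind != "categorical":
        raise MatrixError("expand_categorical requires a categorical matrix")
    out = {}
    for col in matrix.col_ids:
        cells = matrix.data[col]
        cats = sorted(set().union(*cells) if len(cells) else set())
        for cat in cats:
            out[f"{col}={cat}"] = cells.map(lambda s, c=cat: 1.0 if c in s else 0.0)
    return IndexedMatrix(pd.DataFrame(out, index=matrix.data.index), "binary")
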