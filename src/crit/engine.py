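"""The cross-pattern iteration.

The loop: an initial two-class labeling of the first matrix's columns is
transferred to the second matrix's rows (the connector), whose columns are
then discriminated and labeled; those labels transfer to the next matrix,
and so on.  After the final step every column labeled sensitive is paired
with the source feature as a cross pattern, carrying the final step's p and
q, the traversed label path, and the per-step statistics.

Everything here is deterministic: two runs with the same configuration
produce identical results.  A step that yields a single-class labeling
before the chain is exhausted ends the run with a partial result rather
than raising, which keeps property sweeps alive on degenerate data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CrossPattern,
    IndexedMatrix,
    Labeling,
    MatrixChain,
    MatrixError,
    StepResult,
)
from .discriminators import (
    DiscriminatorConfig,
    binary_label,
    discriminate_binary,
    discriminate_continuous,
    median_split_label,
)

log = logging.getLogger(__name__)

#: printed significance tiers used in the original network figures
REGULATORY_TIERS = (1e-4, 1e-3, 0.05)
CHEMOGENOMIC_TIERS = (1e-3, 0.01, 0.05)


def transfer_labels(labeling: Labeling, next_matrix: IndexedMatrix) -> Labeling:
    """Re-bind a column labeling to the next matrix's rows (same index set)."""
    if not labeling.labeled_ids():
        raise ValueError("no labeled rows to transfer")
    if set(labeling.assignments) != set(next_matrix.row_ids):
        raise ValueError("labeling index set does not match the next matrix's rows")
    return Labeling("rows_of_next", dict(labeling.assignments), labeling.label_set)


def significance_tier(p: float, thresholds: Sequence[float]) -> int | None:
    """1-based index of the smallest threshold exceeding p; None if untiered."""
    ts = list(thresholds)
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("tier thresholds must be strictly increasing")
    for i, t in enumerate(ts, start=1):
        if p < t:
            return i
    return None


# ---------------------------------------------------------------------------
# preprocessing

def variance_filter(
    matrix: IndexedMatrix, threshold: float, axis: str = "cols"
) -> IndexedMatrix:
    """Keep rows/columns whose sample variance over non-missing entries
    strictly exceeds ``threshold``.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    np_axis = 1 if axis == "rows" else 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(matrix.data.to_numpy(dtype=float), axis=np_axis, ddof=1)
    keep = np.nan_to_num(var, nan=0.0) > threshold
    if not keep.any():
        raise MatrixError("empty matrix after variance filter")
    if axis == "rows":
        out = matrix.data.loc[keep]
    else:
        out = matrix.data.loc[:, keep]
    log.info("variance filter (>%s, %s): kept %d of %d", threshold, axis, keep.sum(), keep.size)
    return IndexedMatrix(out.copy(), matrix.value_kind)


def drop_rows(matrix: IndexedMatrix, ids: Sequence[str]) -> IndexedMatrix:
    """Remove the named rows; absent identifiers warn instead of failing."""
    present = set(matrix.row_ids)
    absent = [i for i in ids if i not in present]
    if absent:
        warnings.warn(f"drop_rows: identifiers not present: {absent[:10]}", stacklevel=2)
    keep = [i for i in matrix.row_ids if i not in set(ids)]
    if not keep:
        raise MatrixError("empty matrix after dropping all rows")
    return IndexedMatrix(matrix.data.loc[keep].copy(), matrix.value_kind)


def clip_resistance(matrix: IndexedMatrix, mode: str = "exclude") -> IndexedMatrix:
    """Mask entries indicating better-than-reference growth (resistance).

    Under the default sign convention larger values mean a larger fitness
    defect, so negative entries indicate the deletion strain grew *better*
    under treatment; ``mode='exclude'`` sets them missing, ``mode='keep'``
    is the identity.
    """
    if mode == "keep":
        return matrix
    if mode != "exclude":
        raise ValueError("mode must be 'exclude' or 'keep'")
    data = matrix.data.copy()
    data = data.mask(data < 0)
    return IndexedMatrix(data, matrix.value_kind)


# ---------------------------------------------------------------------------
# run configuration and results

@dataclass
class RunConfig:
    """Everything a run needs; a pure value object.

    ``chain`` follows the formal orientation: the first matrix's *columns*
    are the entities the initial labeler labels, and each matrix's columns
    index the next matrix's rows.  ``source_feature`` names the row of the
    first matrix whose values drive the initial labeler (ignored when an
    explicit ``initial_labeling`` is supplied).
    """

    chain: MatrixChain
    source_feature: str = ""
    initial_labeler: str = "median_split"  # median_split | binary | external
    initial_labeling: Labeling | None = None
    hi_label: str = "hi"
    lo_label: str = "lo"
    steps: list[DiscriminatorConfig] = field(default_factory=list)
    tier_thresholds: tuple[float, ...] = REGULATORY_TIERS
    seed: int = 0

    def __post_init__(self) -> None:
        n_steps = len(self.chain) - 1
        if not self.steps:
            self.steps = [DiscriminatorConfig() for _ in range(n_steps)]
        if len(self.steps) != n_steps:
            raise ValueError(
                f"need {n_steps} step configs for a {len(self.chain)}-matrix chain, "
                f"got {len(self.steps)}"
            )


@dataclass
class RunResult:
    """Per-step tables, labelings L0..Ln, cross patterns, and provenance."""

    steps: list[StepResult]
    labelings: list[Labeling]
    cross_patterns: list[CrossPattern]
    halted: bool
    halted_after: int | None
    provenance: dict

    def patterns_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": cp.source_feature,
                "target": cp.target_feature,
                "label_path": "->".join(cp.label_path),
                "final_p": cp.final_p,
                "final_q": cp.final_q,
                "tier": cp.tier if cp.tier is not None else "",
            }
            for cp in self.cross_patterns
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "label_path", "final_p", "final_q", "tier"]
        )


def _initial_labeling(config: RunConfig) -> Labeling:
    m1 = config.chain[0]
    if config.initial_labeler == "external":
        if config.initial_labeling is None:
            raise ValueError("external initial labeler requires initial_labeling")
        return config.initial_labeling
    if config.source_feature not in set(m1.row_ids):
        raise ValueError(
            f"source feature {config.source_feature!r} is not a row of the first matrix"
        )
    values = dict(m1.data.loc[config.source_feature])
    if config.initial_labeler == "median_split":
        return median_split_label(values, "initial", config.hi_label, config.lo_label)
    if config.initial_labeler == "binary":
        return binary_label(values, config.hi_label, config.lo_label, "initial")
    raise ValueError(f"unknown initial labeler {config.initial_labeler!r}")


def run_crit(config: RunConfig) -> RunResult:
    """Execute the full iteration over a validated chain.

    Returns the per-step results, the sequence of labelings, and — when the
    chain completes — the cross patterns pairing the source feature with
    every final-step column labeled sensitive.
    """
    labeling = _initial_labeling(config)
    labelings = [labeling]
    steps: list[StepResult] = []
    halted_after: int | None = None

    for k in range(1, len(config.chain)):
        if len(labeling.present_labels()) < 2:
            halted_after = k - 1
            break
        matrix = config.chain[k]
        row_labeling = transfer_labels(labeling, matrix)
        cfg = config.steps[k - 1]
        if cfg.kind == "hypergeometric":
            step, labeling = discriminate_binary(matrix, row_labeling, cfg, step_index=k)
        else:
            step, labeling = discriminate_continuous(matrix, row_labeling, cfg, step_index=k)
        steps.append(step)
        labelings.append(labeling)

    halted = halted_after is not None
    patterns: list[CrossPattern] = []
    if not halted and steps:
        final = steps[-1]
        sensitive_label = config.steps[-1].sensitive_label
        path_prefix = tuple(l.label_set[0] for l in labelings[:-1])
        for target, row in final.table.iterrows():
            if row["label"] != sensitive_label:
                continue
            p, q = float(row["p_value"]), float(row["q_value"])
            patterns.append(
                CrossPattern(
                    source_feature=config.source_feature,
                    target_feature=str(target),
                    label_path=path_prefix + (sensitive_label,),
                    final_p=p,
                    final_q=q,
                    tier=significance_tier(p, config.tier_thresholds),
                    step_stats=[s.table.loc[target] if target in s.table.index else None
                                for s in steps],
                )
            )

    provenance = {
        "source_feature": config.source_feature,
        "initial_labeler": config.initial_labeler,
        "n_matrices": len(config.chain),
        "steps": [vars(c).copy() for c in config.steps],
        "tier_thresholds": list(config.tier_thresholds),
        "seed": config.seed,
        "halted": halted,
        "halted_after": halted_after,
    }
    return RunResult(steps, labelings, patterns, halted, halted_after, provenance)


def sweep(
    chain: MatrixChain,
    source_features: Sequence[str] | None = None,
    steps: Sequence[DiscriminatorConfig] | None = None,
    tier_thresholds: Sequence[float] = REGULATORY_TIERS,
    initial_labeler: str = "median_split",
) -> dict[str, RunResult]:
    """Run the iteration once per source feature (row of the first matrix).

    Multiple-testing correction stays per run and per step; no correction is
    applied across source features.
    """
    feats = list(source_features) if source_features is not None else chain[0].row_ids
    out: dict[str, RunResult] = {}
    for feat in feats:
        cfg = RunConfig(
            chain=chain,
            source_feature=feat,
            initial_labeler=initial_labeler,
            steps=list(steps) if steps else [],
            tier_thresholds=tuple(tier_thresholds),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[feat] = run_crit(cfg)
    return out
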