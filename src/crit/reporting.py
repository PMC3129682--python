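"""Run summaries: sensitivity profiles, pairwise counts, slice distributions.

A *sensitivity profile* collects, for one entity, its sensitive /
insensitive / untestable status (and p-value) across every source property
of a sweep — the per-protein drug-property sensitivity profile.  Profiles
support overlap comparison (shared sensitive calls, Jaccard), aggregation
into a property x property count table, and extraction of the two labeled
value distributions behind any single call for density plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import IndexedMatrix, Labeling
from .engine import RunResult

STATUSES = ("sensitive", "insensitive", "untestable")


@dataclass
class SensitivityProfile:
    """Per-entity status across a universe of source properties."""

    entity: str
    statuses: dict[str, str]            # property -> sensitive|insensitive|untestable
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.statuses.values() if s not in STATUSES}
        if bad:
            raise ValueError(f"unknown statuses: {sorted(bad)}")

    @property
    def sensitive_set(self) -> frozenset[str]:
        return frozenset(p for p, s in self.statuses.items() if s == "sensitive")


def profiles_from_sweep(
    sweep_results: Mapping[str, RunResult], step: int = 1
) -> dict[str, SensitivityProfile]:
    """Build one profile per entity of the given step's column index.

    Entities whose run halted before the step are marked untestable for that
    property so every profile spans the same property universe.
    """
    entities: list[str] = []
    for res in sweep_results.values():
        if len(res.steps) >= step:
            entities = list(map(str, res.steps[step - 1].table.index))
            break
    if not entities:
        raise ValueError("no run reached the requested step")

    profiles = {
        e: SensitivityProfile(e, {}, {}) for e in entities
    }
    for prop, res in sweep_results.items():
        if len(res.steps) < step:
            for e in entities:
                profiles[e].statuses[prop] = "untestable"
                profiles[e].p_values[prop] = float("nan")
            continue
        table = res.steps[step - 1].table
        sens_label = _sens_name(table)
        for e in entities:
            row = table.loc[e]
            if not bool(row["testable"]):
                profiles[e].statuses[prop] = "untestable"
            else:
                profiles[e].statuses[prop] = (
                    "sensitive" if str(row["label"]) == sens_label else "insensitive"
                )
            profiles[e].p_values[prop] = float(row["p_value"])
    return profiles


def _sens_name(table: pd.DataFrame) -> str:
    # the sensitive label is whichever label co-occurs with q < alpha calls;
    # by construction discriminators use 'sensitive'/'insensitive'
    labels = set(table["label"])
    for cand in labels:
        if "insensitive" not in str(cand) and "sensitive" in str(cand):
            return str(cand)
    return "sensitive"


def profile_overlap(a: SensitivityProfile, b: SensitivityProfile) -> tuple[int, float]:
    """(shared sensitive count, Jaccard of the sensitive sets); 0/0 -> 0."""
    if set(a.statuses) != set(b.statuses):
        raise ValueError("profiles cover different property universes")
    sa, sb = a.sensitive_set, b.sensitive_set
    shared = len(sa & sb)
    union = len(sa | sb)
    return shared, (shared / union if union else 0.0)


def count_matrix(profiles: Mapping[str, SensitivityProfile]) -> pd.DataFrame:
    """Property x property table of sensitive-entity counts.

    Diagonal: entities sensitive to that property; off-diagonal: entities
    sensitive to both (symmetric pairwise intersections).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    universes = {frozenset(p.statuses) for p in profiles.values()}
    if len(universes) != 1:
        raise ValueError("profiles cover different property universes")
    props = sorted(next(iter(universes)))
    indicator = pd.DataFrame(
        {e: {p: (p in prof.sensitive_set) for p in props} for e, prof in profiles.items()}
    ).T.astype(int)
    counts = indicator.T @ indicator
    return counts.loc[props, props]


def density_pair(
    connector: IndexedMatrix,
    column: str,
    labeling: Labeling,
    n_bins: int = 64,
) -> tuple[np.ndarray, np.ndarray, float]:
    """The hi- and lo-slice value vectors of one connector column, plus
    their histogram overlap coefficient.

    The overlap is the integrated minimum of the two per-slice histograms on
    a shared ``n_bins``-bin grid spanning the pooled range: 1 for identical
    distributions, 0 for disjoint supports.
    """
    if column not in set(connector.col_ids):
        raise ValueError(f"column {column!r} not in connector")
    if len(labeling.label_set) != 2:
        raise ValueError("density_pair requires a two-label labeling")
    la, lb = labeling.label_set
    vals = connector.data[column]
    xa = vals.loc[[i for i in connector.row_ids if labeling.assignments.get(i) == la]]
    xb = vals.loc[[i for i in connector.row_ids if labeling.assignments.get(i) == lb]]
    xa = xa.to_numpy(dtype=float)
    xb = xb.to_numpy(dtype=float)
    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty slice for column " + repr(column))
    lo = min(xa.min(), xb.min())
    hi = max(xa.max(), xb.max())
    if lo == hi:
        return xa, xb, 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(xa, bins=edges)
    hb, _ = np.histogram(xb, bins=edges)
    overlap = float(np.minimum(ha / len(xa), hb / len(xb)).sum())
    return xa, xb, overlap


def patterns_markdown(results: Mapping[str, RunResult]) -> str:
    """Tiered cross-pattern summary, one row per pattern."""
    lines = [
        "| source property | target feature | P | tier |",
        "| --- | --- | --- | --- |",
    ]
    for prop, res in results.items():
        for cp in res.cross_patterns:
            tier = str(cp.tier) if cp.tier is not None else "-"
            lines.append(f"| {cp.source_feature} | {cp.target_feature} | {cp.final_p:.3g} | {tier} |")
    return "\n".join(lines) + "\n"
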