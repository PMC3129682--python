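"""Synthetic matrix chains with implanted ground-truth cross patterns.

The generator emulates the chemogenomic chain structure: a source-property
table (one continuous property per source entity, e.g. a molecular
descriptor per drug), a continuous connector (source x mid fitness-defect
scores), and a final feature table (mid x final, e.g. protein properties).
Signal is planted as Gaussian mean shifts: *sensitive* mid columns of the
connector are shifted by ``effect_size * noise_sd`` for hi-labeled sources,
and *informative* final features are shifted by ``final_effect_size`` for
the truly sensitive mid entities.  Gaussian noise keeps the Welch-based
discriminator's power and false-discovery behaviour analytically checkable.

Source labels are assigned 50/50 first and the continuous source property is
then drawn consistent with them (hi strictly above the eventual median), so
the median-split labeler recovers the planted labels exactly and the whole
path — labeler, transfer, slicing, testing — is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IndexedMatrix, Labeling, MatrixChain, build_chain
from .discriminators import DiscriminatorConfig
from .engine import RunConfig, RunResult, run_crit


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chain.

    Defaults describe a moderately sized chemogenomic-style study: 100
    sources split 50/50, 200 mid entities of which a quarter respond with a
    3-SD connector shift, and 50 final features of which a quarter separate
    the sensitive mid entities with a 2-unit shift on unit noise.
    """

    n_sources: int = 100
    n_mid: int = 200
    n_final_features: int = 50
    effect_size: float = 3.0
    frac_sensitive_mid: float = 0.25
    final_effect_size: float = 2.0
    frac_informative_final: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0
    source_feature: str = "source_prop"
    binary_connector: bool = False
    base_rate: float = 0.1      # binary variant: 1-rate for unaffected cells
    shifted_rate: float = 0.9   # binary variant: 1-rate for hi x sensitive cells

    def __post_init__(self) -> None:
        for frac in (self.frac_sensitive_mid, self.frac_informative_final):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_sources, self.n_mid, self.n_final_features) < 4:
            raise ValueError("all dimensions must be >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.frac_sensitive_mid > 0 and round(self.frac_sensitive_mid * self.n_mid) == 0:
            raise ValueError("frac_sensitive_mid rounds to zero planted columns")
        if (self.frac_informative_final > 0
                and round(self.frac_informative_final * self.n_final_features) == 0):
            raise ValueError("frac_informative_final rounds to zero planted features")


@dataclass
class GroundTruth:
    """What was planted: source labels and the truly responsive feature sets."""

    source_labels: dict[str, str]
    sensitive_mid: frozenset[str]
    informative_final: frozenset[str]


def generate_chain(spec: SyntheticSpec) -> tuple[MatrixChain, Labeling, GroundTruth]:
    """Build a three-matrix chain with planted effects, reproducibly from seed.

    Returns the validated chain (source-property table in the formal
    orientation, property rows x source columns), the initial hi/lo labeling
    the median split recovers, and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    sources = [f"s{i:04d}" for i in range(spec.n_sources)]
    mids = [f"m{i:04d}" for i in range(spec.n_mid)]
    finals = [f"f{i:03d}" for i in range(spec.n_final_features)]

    n_hi = spec.n_sources // 2
    order = rng.permutation(spec.n_sources)
    hi_mask = np.zeros(spec.n_sources, dtype=bool)
    hi_mask[order[:n_hi]] = True

    # property values: lo strictly below 0, hi strictly above, so the median
    # with a 50/50 (or off-by-one) split lies between the two groups
    prop = np.where(hi_mask, 0.1 + np.abs(rng.normal(size=spec.n_sources)),
                    -0.1 - np.abs(rng.normal(size=spec.n_sources)))
    m1 = IndexedMatrix(
        pd.DataFrame([prop], index=[spec.source_feature], columns=sources), "continuous"
    )

    n_sens = round(spec.frac_sensitive_mid * spec.n_mid)
    sens_idx = rng.choice(spec.n_mid, size=n_sens, replace=False)
    sens_mask = np.zeros(spec.n_mid, dtype=bool)
    sens_mask[sens_idx] = True

    if spec.binary_connector:
        rate = np.full((spec.n_sources, spec.n_mid), spec.base_rate)
        rate[np.ix_(hi_mask, sens_mask)] = spec.shifted_rate
        conn = (rng.random((spec.n_sources, spec.n_mid)) < rate).astype(float)
        conn_kind = "binary"
    else:
        conn = rng.normal(scale=spec.noise_sd, size=(spec.n_sources, spec.n_mid))
        conn[np.ix_(hi_mask, sens_mask)] += spec.effect_size * spec.noise_sd
        conn_kind = "continuous"
    m2 = IndexedMatrix(pd.DataFrame(conn, index=sources, columns=mids), conn_kind)

    n_inf = round(spec.frac_informative_final * spec.n_final_features)
    inf_idx = rng.choice(spec.n_final_features, size=n_inf, replace=False)
    inf_mask = np.zeros(spec.n_final_features, dtype=bool)
    inf_mask[inf_idx] = True
    final = rng.normal(size=(spec.n_mid, spec.n_final_features))
    final[np.ix_(sens_mask, inf_mask)] += spec.final_effect_size
    m3 = IndexedMatrix(pd.DataFrame(final, index=mids, columns=finals), "continuous")

    chain = build_chain([m1, m2, m3])
    labels = {s: ("hi" if h else "lo") for s, h in zip(sources, hi_mask)}
    labeling = Labeling("initial", dict(labels), ("hi", "lo"))
    truth = GroundTruth(
        source_labels=labels,
        sensitive_mid=frozenset(np.array(mids)[sens_mask]),
        informative_final=frozenset(np.array(finals)[inf_mask]),
    )
    return chain, labeling, truth


def run_synthetic(spec: SyntheticSpec,
                  steps: Sequence[DiscriminatorConfig] | None = None) -> tuple[RunResult, GroundTruth]:
    """Generate a chain and run the full iteration on it."""
    chain, _, truth = generate_chain(spec)
    step_cfgs = list(steps) if steps is not None else []
    if not step_cfgs:
        kinds = ["hypergeometric" if spec.binary_connector else "welch", "welch"]
        step_cfgs = [DiscriminatorConfig(kind=k) for k in kinds]
    cfg = RunConfig(
        chain=chain,
        source_feature=spec.source_feature,
        steps=step_cfgs,
        seed=spec.seed,
    )
    return run_crit(cfg), truth


def evaluate_recovery(detected: set, truth: set) -> tuple[float, float]:
    """(power, fdr) of a detected identifier set against the planted truth.

    power = |detected & truth| / |truth| (0 when truth is empty);
    fdr = |detected - truth| / |detected| (0 when nothing was detected).
    """
    detected, truth = set(detected), set(truth)
    power = len(detected & truth) / len(truth) if truth else 0.0
    fdr = len(detected - truth) / len(detected) if detected else 0.0
    return power, fdr


def power_curve(
    base_spec: SyntheticSpec,
    effect_sizes: Sequence[float],
    n_reps: int = 10,
    seed: int = 0,
    step: int = 1,
) -> pd.DataFrame:
    """Empirical recovery over a grid of connector effect sizes.

    Runs ``n_reps`` independent replicates per grid point and measures power
    and FDR of the step-``step`` sensitive set against the planted truth.
    Returns a table with Monte-Carlo standard errors of the mean power.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for delta in effect_sizes:
        powers, fdrs = [], []
        for _ in range(n_reps):
            spec = replace(base_spec, effect_size=float(delta),
                           seed=int(rng.integers(2**31)))
            result, truth = run_synthetic(spec)
            detected = _sensitive_set(result, step)
            truth_set = truth.sensitive_mid if step == 1 else truth.informative_final
            pw, fd = evaluate_recovery(detected, truth_set)
            powers.append(pw)
            fdrs.append(fd)
        rows.append(
            {
                "effect_size": float(delta),
                "power_mean": float(np.mean(powers)),
                "power_se": float(np.std(powers, ddof=1) / np.sqrt(n_reps)),
                "fdr_mean": float(np.mean(fdrs)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def _sensitive_set(result: RunResult, step: int) -> set[str]:
    if result.halted and len(result.steps) < step:
        return set()
    table = result.steps[step - 1].table
    sensitive = table.index[table["label"] == "sensitive"]
    return set(map(str, sensitive))
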