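import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crit.core import IndexedMatrix, Labeling
from crit.discriminators import (
    DegenerateSplitWarning,
    DiscriminatorConfig,
    UntestableColumn,
    bh_fdr,
    binary_label,
    discriminate_binary,
    discriminate_continuous,
    expand_categorical,
    hypergeom_tail,
    median_split_label,
    sensitivity_score,
    slice_rows,
    welch_t,
)

# ---------------------------------------------------------------------------
# independent oracles

def bh_step_up_oracle(p):
    """Hand-executed BH step-up: q_(i) = min_{j>=i} m * p_(j) / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def hypergeom_enumeration(x, m, n, k):
    """Exhaustive draw enumeration: fraction of k-subsets of the m+n balls
    containing at least x of the m white balls."""
    balls = [1] * m + [0] * n
    total = hit = 0
    for draw in itertools.combinations(range(m + n), k):
        total += 1
        if sum(balls[i] for i in draw) >= x:
            hit += 1
    return hit / total if total else 0.0


# ---------------------------------------------------------------------------
# labelers

class TestMedianSplit:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ({"a": 1, "b": 2, "c": 3, "d": 4}, {"a": "lo", "b": "lo", "c": "hi", "d": "hi"}),
            ({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5},
             {"a": "lo", "b": "lo", "c": "lo", "d": "hi", "e": "hi"}),
        ],
    )
    def test_split_with_ties_at_median_going_lo(self, values, expected):
        lab = median_split_label(values)
        assert lab.assignments == expected

    def test_all_identical_values_all_lo_with_warning(self):
        with pytest.warns(DegenerateSplitWarning):
            lab = median_split_label({"a": 7, "b": 7, "c": 7})
        assert set(lab.assignments.values()) == {"lo"}

    def test_missing_values_left_unlabeled(self):
        lab = median_split_label({"a": 1.0, "b": float("nan"), "c": 3.0})
        assert lab.assignments["b"] is None

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            median_split_label({"a": 1.0})

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True))
    def test_hi_iff_strictly_above_median(self, vals):
        values = {f"k{i}": v for i, v in enumerate(vals)}
        med = float(np.median(vals))
        lab = median_split_label(values)
        for k, v in values.items():
            assert lab.assignments[k] == ("hi" if v > med else "lo")


class TestBinaryLabel:
    def test_maps_one_and_zero(self):
        lab = binary_label({"d1": 1, "d2": 0}, "aromatic", "non-aromatic")
        assert lab.assignments == {"d1": "aromatic", "d2": "non-aromatic"}

    def test_single_class_warns(self):
        with pytest.warns(DegenerateSplitWarning):
            binary_label({"d1": 1, "d2": 1}, "a", "b")

    def test_non_binary_value_rejected(self):
        with pytest.raises(ValueError):
            binary_label({"d1": 0.5}, "a", "b")


class TestSliceRows:
    def test_partition_by_label(self, small_matrix):
        m = IndexedMatrix(
            pd.DataFrame(np.arange(8.0).reshape(4, 2),
                         index=list("abcd"), columns=["c1", "c2"])
        )
        lab = Labeling("rows", {"a": "hi", "b": "lo", "c": "hi", "d": "lo"}, ("hi", "lo"))
        slices = slice_rows(m, lab)
        assert slices["hi"].row_ids == ["a", "c"]
        assert slices["lo"].row_ids == ["b", "d"]
        assert slices["hi"].col_ids == ["c1", "c2"]

    def test_single_label_gives_empty_other_slice(self, small_matrix):
        lab = Labeling("rows", {"r1": "hi", "r2": "hi"}, ("hi", "lo"))
        slices = slice_rows(small_matrix, lab)
        assert slices["lo"].shape == (0, 2)

    def test_unlabeled_rows_in_no_slice(self, small_matrix):
        lab = Labeling("rows", {"r1": "hi", "r2": None}, ("hi", "lo"))
        slices = slice_rows(small_matrix, lab)
        assert slices["hi"].row_ids == ["r1"]
        assert slices["lo"].shape[0] == 0


# ---------------------------------------------------------------------------
# elementary statistics

class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_derived_example(self):
        # se^2 = 1/3 + 4/3, df = (5/3)^2 / ((1/3)^2/2 + (4/3)^2/2)
        r = welch_t([1, 2, 3], [2, 4, 6])
        assert r.t == pytest.approx(-2.0 / math.sqrt(5.0 / 3.0), rel=1e-12)
        assert r.df == pytest.approx((5 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2), rel=1e-12)

    def test_degenerate_variance_untestable(self):
        with pytest.raises(UntestableColumn, match="degenerate variance"):
            welch_t([1, 1], [2, 2])

    def test_undersized_sample_untestable(self):
        with pytest.raises(UntestableColumn, match="min_group_size"):
            welch_t([1], [2, 3])

    def test_agrees_with_scipy_on_random_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
            r = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert r.t == pytest.approx(ref.statistic, rel=1e-10)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10),
        st.lists(st.floats(-100, 100), min_size=3, max_size=10),
    )
    def test_antisymmetric_in_sample_order(self, x, y):
        try:
            r1 = welch_t(x, y)
            r2 = welch_t(y, x)
        except UntestableColumn:
            return
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)


class TestSensitivityScore:
    def test_printed_formula_substitution(self):
        # mean 2, se 0.5 vs mean 1, se 0.25 -> (2-1)/(0.5-0.25) = 4
        x_hi = [1.5, 2.5]    # n=2: sd = 0.5*sqrt(2), se = 0.5
        x_lo = [0.75, 1.25]  # se = 0.25
        assert sensitivity_score(x_hi, x_lo) == pytest.approx(4.0, rel=1e-12)

    def test_equal_standard_errors_undefined(self):
        assert math.isnan(sensitivity_score([1, 2, 3], [1, 2, 3]))

    def test_zero_mean_difference_unequal_se(self):
        assert sensitivity_score([0, 0, 0, 0], [-2, 2]) == 0.0


class TestHypergeomTail:
    def test_full_tail_is_one(self):
        assert hypergeom_tail(0, 5, 3, 4) == 1.0

    def test_two_white_from_two_two_urn(self):
        # exactly 1 of the C(4,2)=6 equally likely draws holds both whites
        assert hypergeom_tail(2, 2, 2, 2) == pytest.approx(1 / 6, rel=1e-12)

    def test_impossible_count_is_zero(self):
        assert hypergeom_tail(3, 2, 5, 2) == 0.0

    def test_guaranteed_count_is_one(self):
        assert hypergeom_tail(2, 5, 1, 3) == 1.0

    def test_matches_exhaustive_enumeration_small_urns(self):
        for m in range(0, 7):
            for n in range(0, 7):
                if m + n == 0:
                    continue
                for k in range(0, m + n + 1):
                    for x in range(0, k + 1):
                        assert hypergeom_tail(x, m, n, k) == pytest.approx(
                            hypergeom_enumeration(x, m, n, k), abs=1e-12
                        ), (x, m, n, k)


class TestBhFdr:
    def test_singleton_identity(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_p_values_map_to_themselves(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from([0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 0.77, 1.0]),
                    min_size=1, max_size=6))
    def test_matches_step_up_oracle(self, p):
        assert list(bh_fdr(p)) == pytest.approx(bh_step_up_oracle(p), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8), st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        q = bh_fdr(p)
        q_perm = bh_fdr([p[i] for i in idx])
        assert [q[i] for i in idx] == pytest.approx(list(q_perm), rel=1e-12)


# ---------------------------------------------------------------------------
# discriminators

class TestDiscriminateContinuous:
    def test_forced_separation(self, separated_matrix):
        m, lab = separated_matrix
        step, out = discriminate_continuous(m, lab)
        assert step.table.loc["c1", "label"] == "sensitive"
        assert step.table.loc["c2", "label"] == "insensitive"
        assert out.assignments == {"c1": "sensitive", "c2": "insensitive"}

    def test_matches_column_wise_scalar_welch(self, separated_matrix):
        m, lab = separated_matrix
        step, _ = discriminate_continuous(m, lab)
        hi = m.data.loc[[r for r, l in lab.assignments.items() if l == "hi"]]
        lo = m.data.loc[[r for r, l in lab.assignments.items() if l == "lo"]]
        for col in m.col_ids:
            ref = welch_t(hi[col], lo[col])
            assert step.table.loc[col, "score"] == pytest.approx(ref.t, rel=1e-12)
            assert step.table.loc[col, "p_value"] == pytest.approx(ref.p, rel=1e-12)

    def test_single_label_everything_untestable(self, small_matrix):
        lab = Labeling("rows", {"r1": "hi", "r2": "hi"}, ("hi", "lo"))
        step, _ = discriminate_continuous(small_matrix, lab)
        assert not step.table["testable"].any()
        assert set(step.table["reason"]) == {"min_group_size"}

    def test_all_missing_slice_untestable_with_reason(self):
        rows = [f"r{i}" for i in range(8)]
        data = pd.DataFrame({"c1": np.r_[[np.nan] * 4, [1.0, 2.0, 3.0, 4.0]]}, index=rows)
        lab = Labeling("rows", {r: ("hi" if i < 4 else "lo") for i, r in enumerate(rows)},
                       ("hi", "lo"))
        step, _ = discriminate_continuous(IndexedMatrix(data), lab)
        assert not step.table.loc["c1", "testable"]
        assert step.table.loc["c1", "reason"] == "min_group_size"

    def test_untestable_columns_excluded_from_correction(self, separated_matrix):
        m, lab = separated_matrix
        with_extra = IndexedMatrix(m.data.assign(c3=np.nan))
        step, _ = discriminate_continuous(with_extra, lab)
        testable_q = step.table.loc[step.table["testable"], "q_value"]
        assert testable_q.notna().all()
        assert np.isnan(step.table.loc["c3", "q_value"])
        assert step.table.loc["c3", "label"] == "insensitive"

    def test_uncorrected_mode_uses_raw_p(self, separated_matrix):
        m, lab = separated_matrix
        cfg = DiscriminatorConfig(correction="none")
        step, _ = discriminate_continuous(m, lab, cfg)
        assert step.table["q_value"].tolist() == pytest.approx(
            step.table["p_value"].tolist()
        )


class TestDiscriminateBinary:
    def test_perfect_association_single_term_tail(self):
        rows = [f"r{i}" for i in range(20)]
        vals = np.r_[np.ones(10), np.zeros(10)]
        m = IndexedMatrix(pd.DataFrame({"c": vals}, index=rows), "binary")
        lab = Labeling("rows", {r: ("A" if i < 10 else "B") for i, r in enumerate(rows)},
                       ("A", "B"))
        step, out = discriminate_binary(m, lab)
        assert step.table.loc["c", "p_value"] == pytest.approx(1 / math.comb(20, 10), rel=1e-12)
        assert out.assignments["c"] == "sensitive"

    def test_constant_one_column_insensitive(self):
        rows = [f"r{i}" for i in range(12)]
        m = IndexedMatrix(pd.DataFrame({"c": np.ones(12)}, index=rows), "binary")
        lab = Labeling("rows", {r: ("A" if i < 6 else "B") for i, r in enumerate(rows)},
                       ("A", "B"))
        step, _ = discriminate_binary(m, lab)
        assert step.table.loc["c", "p_value"] == 1.0
        assert step.table.loc["c", "label"] == "insensitive"

    def test_balanced_column_not_significant(self):
        # 3 of 6 ones in each slice: enumeration gives a large tail
        rows = [f"r{i}" for i in range(12)]
        vals = np.r_[[1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]].astype(float)
        m = IndexedMatrix(pd.DataFrame({"c": vals}, index=rows), "binary")
        lab = Labeling("rows", {r: ("A" if i < 6 else "B") for i, r in enumerate(rows)},
                       ("A", "B"))
        step, _ = discriminate_binary(m, lab)
        expected = hypergeom_enumeration(3, 6, 6, 6)
        assert step.table.loc["c", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert step.table.loc["c", "label"] == "insensitive"

    def test_requires_binary_matrix(self, small_matrix, hi_lo_labeling):
        with pytest.raises(Exception, match="binary"):
            discriminate_binary(small_matrix, hi_lo_labeling)


class TestExpandCategorical:
    def test_one_column_per_category_sorted(self):
        df = pd.DataFrame({"loc": ["nucleus", "golgi", "nucleus"]},
                          index=["p1", "p2", "p3"])
        m = IndexedMatrix(df, "categorical")
        out = expand_categorical(m)
        assert out.col_ids == ["loc=golgi", "loc=nucleus"]
        assert out.data["loc=nucleus"].tolist() == [1.0, 0.0, 1.0]
        assert out.data["loc=golgi"].tolist() == [0.0, 1.0, 0.0]

    def test_multi_localisation_sets_both_columns(self):
        df = pd.DataFrame({"loc": ["nucleus,vacuole", "golgi"]}, index=["p1", "p2"])
        m = IndexedMatrix(df, "categorical")
        out = expand_categorical(m)
        assert out.data.loc["p1", "loc=nucleus"] == 1.0
        assert out.data.loc["p1", "loc=vacuole"] == 1.0

    def test_empty_cell_all_zero(self):
        df = pd.DataFrame({"loc": ["nucleus", ""]}, index=["p1", "p2"])
        out = expand_categorical(IndexedMatrix(df, "categorical"))
        assert out.data.loc["p2"].sum() == 0.0
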