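import numpy as np
import pandas as pd
import pytest

from crit.core import IndexedMatrix, Labeling, build_chain


@pytest.fixture
def small_matrix():
    return IndexedMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["r1", "r2"], columns=["c1", "c2"]
        )
    )


@pytest.fixture
def hi_lo_labeling():
    return Labeling("rows", {"a": "hi", "b": "lo", "c": "hi", "d": "lo"}, ("hi", "lo"))


@pytest.fixture
def separated_matrix():
    """60 rows x 2 cols: c1 separates hi/lo rows overwhelmingly, c2 is null."""
    rng = np.random.default_rng(7)
    rows = [f"r{i}" for i in range(60)]
    labels = {r: ("hi" if i < 30 else "lo") for i, r in enumerate(rows)}
    c1 = np.where(np.arange(60) < 30, 10.0, 0.0) + rng.normal(scale=0.01, size=60)
    c2 = rng.normal(size=60)
    m = IndexedMatrix(pd.DataFrame({"c1": c1, "c2": c2}, index=rows))
    return m, Labeling("rows", labels, ("hi", "lo"))


@pytest.fixture
def tiny_chain():
    """Three matrices in formal orientation: props x drugs, drugs x proteins,
    proteins x protein-props."""
    m1 = IndexedMatrix(
        pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["MW"],
                     columns=["d1", "d2", "d3", "d4"])
    )
    rng = np.random.default_rng(0)
    m2 = IndexedMatrix(
        pd.DataFrame(rng.normal(size=(4, 3)), index=["d1", "d2", "d3", "d4"],
                     columns=["p1", "p2", "p3"])
    )
    m3 = IndexedMatrix(
        pd.DataFrame(rng.normal(size=(3, 2)), index=["p1", "p2", "p3"],
                     columns=["GRAVY", "abundance"])
    )
    return build_chain([m1, m2, m3])
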