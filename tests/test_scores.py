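import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency
from scipy.stats import entropy as scipy_entropy

from oracles import loop_complexity, loop_max_complexity, loop_rs
from rsdc import (
    ContingencyTable,
    chi2_2x2_corrected,
    chi2_2xr_pearson,
    chi2_auto,
    complexity,
    entropy,
    max_complexity,
    relative_simplicity,
    score_backend,
    score_table,
)


def T(rows):
    return ContingencyTable(np.array(rows, dtype=float))


# -- entropy ----------------------------------------------------------------


def test_entropy_of_binary_frequency():
    assert entropy([3, 7]) == pytest.approx(0.8813, abs=5e-5)


def test_entropy_ignores_scale():
    assert entropy([30, 70]) == entropy([3, 7])


def test_entropy_degenerate_and_invalid():
    assert entropy([5, 0]) == 0.0
    with pytest.raises(ValueError):
        entropy([0, 0])


@given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(sum))
def test_entropy_matches_scipy(counts):
    assert entropy(counts) == pytest.approx(
        float(scipy_entropy(np.array(counts, dtype=float), base=2)),
        abs=1e-12,
    )


# -- complexity and its maximum --------------------------------------------


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([[4, 0], [0, 4]], (0.0, 0.0, 0.0)),
        ([[2, 2], [2, 2]], (8.0, 8.0, 16.0)),
        ([[0, 4], [0, 4]], (0.0, 8.0, 8.0)),
    ],
)
def test_complexity_worked_examples(rows, expected):
    assert complexity(T(rows)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([[4, 0], [0, 4]], (8.0, 8.0, 16.0)),
        ([[2, 1], [3, 4]], (10.0, 8.812908992306927, 18.812908992306927)),
        ([[3, 5], [0, 0]], (8.0, 0.0, 8.0)),  # empty class row
    ],
)
def test_max_complexity_worked_examples(rows, expected):
    assert max_complexity(T(rows)) == pytest.approx(expected)


# -- relative simplicity ----------------------------------------------------


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([[4, 0], [0, 4]], 1.0),
        ([[0, 4], [4, 0]], 1.0),
        ([[2, 2], [2, 2]], 0.0),
        ([[1, 1, 1, 1], [1, 1, 1, 1]], 0.0),
    ],
)
def test_rs_extremes(rows, expected):
    assert relative_simplicity(T(rows)) == expected


def test_rs_degenerate_table_is_zero():
    # single column: C_max = n log2(1) + 0 = 0 for a one-class margin
    assert relative_simplicity(T([[3.0], [0.0]])) == 0.0


def _all_2x2_tables(n_max):
    for n in range(2, n_max + 1):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d >= 0:
                yield np.array([[a, b], [c, d]], dtype=float)


def test_rs_on_enumerated_tables_matches_literal_oracle_and_bounds():
    count = 0
    for counts in _all_2x2_tables(12):
        rs = relative_simplicity(ContingencyTable(counts))
        assert rs == loop_rs(counts)
        assert 0.0 <= rs <= 1.0
        c = complexity(ContingencyTable(counts))
        m = max_complexity(ContingencyTable(counts))
        assert c == pytest.approx(loop_complexity(counts), abs=1e-12)
        assert m == pytest.approx(loop_max_complexity(counts), abs=1e-12)
        assert c.C <= m.C_max + 1e-9
        count += 1
    assert count > 1500  # every 2x2 composition of n = 2..12


def test_rs_increases_towards_class_purity():
    # fixed balanced margins; k above 3 moves mass into class-pure columns
    values = [
        relative_simplicity(T([[k, 6 - k], [6 - k, k]])) for k in range(3, 7)
    ]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_rs_invariant_under_row_and_column_permutation(rng):
    for _ in range(20):
        counts = rng.integers(0, 9, size=(2, 4)).astype(float)
        if counts.sum() == 0:
            continue
        rs = relative_simplicity(ContingencyTable(counts))
        perm = rng.permutation(4)
        assert relative_simplicity(ContingencyTable(counts[:, perm])) == (
            pytest.approx(rs, abs=1e-12)
        )
        assert relative_simplicity(ContingencyTable(counts[::-1])) == (
            pytest.approx(rs, abs=1e-12)
        )


def test_scaling_counts_moves_complexity_but_not_rs_extremes():
    pure, flat = T([[4, 0], [0, 4]]), T([[2, 2], [2, 2]])
    pure10 = T(np.asarray(pure.counts) * 10)
    flat10 = T(np.asarray(flat.counts) * 10)
    assert relative_simplicity(pure10) == 1.0
    assert relative_simplicity(flat10) == 0.0
    # the components themselves scale (the frequency information entropy
    # discards), more than tenfold because the log terms grow too
    assert complexity(flat10).C > complexity(flat).C
    assert max_complexity(flat10).C_max > max_complexity(flat).C_max


# -- chi-square -------------------------------------------------------------


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([[4, 0], [0, 4]], 4.5),
        ([[0, 4], [4, 0]], 4.5),
        ([[2, 2], [2, 2]], 0.5),
        ([[0, 4], [0, 4]], 0.0),  # empty column margin
        ([[0, 0], [4, 4]], 0.0),  # empty row margin
    ],
)
def test_corrected_2x2_simulation_values(rows, expected):
    assert chi2_2x2_corrected(T(rows)).chi_square == expected


@pytest.mark.parametrize(
    "rows,pvalue",
    [
        ([[2, 9], [10, 1]], 0.0027),
        ([[41, 3], [19, 1]], 0.7806),  # corrected term negative, not floored
    ],
)
def test_corrected_2x2_real_data_pvalues(rows, pvalue):
    assert chi2_2x2_corrected(T(rows)).p_value == pytest.approx(
        pvalue, abs=5e-5
    )


def test_floored_variant_matches_scipy_yates(rng):
    for _ in range(50):
        counts = rng.integers(1, 12, size=(2, 2)).astype(float)
        ours = chi2_2x2_corrected(T(counts), correction="yates")
        ref = chi2_contingency(counts, correction=True)
        assert ours.chi_square == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_uncorrected_variant_matches_scipy_pearson(rng):
    for _ in range(50):
        counts = rng.integers(1, 12, size=(2, 4)).astype(float)
        ours = chi2_2xr_pearson(T(counts))
        ref = chi2_contingency(counts, correction=False)
        assert ours.chi_square == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


@pytest.mark.parametrize(
    "rows,stat,pvalue",
    [
        ([[2, 0, 0, 2], [0, 2, 2, 0]], 8.0, None),
        ([[3, 1, 1, 6], [0, 0, 0, 11]], None, 0.0908),
        ([[18, 11, 10, 5], [0, 2, 1, 17]], None, 2.0716e-7),
    ],
)
def test_pearson_2x4_worked_examples(rows, stat, pvalue):
    res = chi2_2xr_pearson(T(rows))
    if stat is not None:
        assert res.chi_square == pytest.approx(stat, abs=1e-12)
    if pvalue is not None:
        assert res.p_value == pytest.approx(pvalue, rel=5e-4)


def test_margin_proportional_table_scores_zero():
    assert chi2_2xr_pearson(T([[2, 4, 6, 8], [1, 2, 3, 4]])).chi_square == (
        pytest.approx(0.0)
    )


def test_sparse_pair_table_collapses_to_corrected_2x2():
    # two occupied columns behave exactly like the 2x2 case ...
    assert chi2_auto(T([[0, 0, 4, 0], [0, 4, 0, 0]])).chi_square == 4.5
    assert chi2_auto(T([[2, 0, 0, 2], [2, 0, 0, 2]])).chi_square == 0.5
    # ... while fully occupied tables keep the Pearson statistic
    assert chi2_auto(T([[2, 0, 0, 2], [0, 2, 2, 0]])).chi_square == 8.0
    assert chi2_auto(T([[3, 1, 1, 6], [0, 0, 0, 11]])).p_value == (
        pytest.approx(0.0908, abs=5e-5)
    )


# -- backends ---------------------------------------------------------------


def test_backend_dispatch_and_values():
    pure, flat = T([[4, 0], [0, 4]]), T([[2, 2], [2, 2]])
    assert score_backend("rs")(pure) == 1.0
    assert score_backend("chi2")(pure) == 4.5
    assert score_backend("entropy")(flat) == 0.0
    assert score_backend("entropy")(pure) == 1.0
    with pytest.raises(ValueError):
        score_backend("gini")


def test_entropy_backend_ignores_scale_where_rs_does_not():
    t1 = T([[3, 1], [1, 3]])
    t10 = T(np.asarray(t1.counts) * 10)
    ent = score_backend("entropy")
    assert ent(t10) == pytest.approx(ent(t1), abs=1e-12)
    # same event ratios, larger frequencies: RS grows toward certainty
    assert relative_simplicity(t10) > relative_simplicity(t1)


def test_chi2_backend_correction_switch():
    degenerate = T([[41, 3], [19, 1]])
    nofloor = score_backend("chi2")(degenerate)
    floored = score_backend("chi2", chi2_correction="yates")(degenerate)
    assert nofloor == pytest.approx(0.07757575757575758)
    assert floored == 0.0


def test_score_table_is_consistent_bundle():
    res = score_table(T([[3, 1], [1, 3]]))
    assert res.C == pytest.approx(res.C_row + res.C_column)
    assert res.C_max == pytest.approx(res.C_row_max + res.C_column_max)
    assert res.RS == pytest.approx((res.C_max - res.C) / res.C_max)
    assert 0.0 <= res.p_value <= 1.0
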