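import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from oracles import loop_rs_net
from rsdc import (
    BinaryTask,
    ConfusionCounts,
    ExpressionDataset,
    binarize,
    dc_predict_binary,
    forward_select,
    integrated_rank,
    mcc,
    rs_net,
    rs_pair,
    generate,
    SyntheticSpec,
)
from rsdc.selection import _loocv_predictions
from rsdc.scores import score_backend


def _task(values, labels):
    d = ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(len(values))],
        gene_ids=[f"g{j}" for j in range(np.shape(values)[1])],
        values=values,
        labels=labels,
    )
    return binarize(d)[0]


# -- MCC --------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(5, 5, 0, 0), 1.0),
        (ConfusionCounts(2, 2, 2, 2), 0.0),
        (ConfusionCounts(4, 3, 1, 2), 10 / np.sqrt(600)),
        (ConfusionCounts(0, 5, 0, 5), 0.0),  # empty predicted-positive margin
    ],
)
def test_mcc_worked_examples(counts, expected):
    assert mcc(counts) == pytest.approx(expected, abs=1e-12)


def test_mcc_matches_sklearn(rng):
    for _ in range(30):
        truth = rng.integers(0, 2, size=20).astype(bool)
        pred = rng.integers(0, 2, size=20).astype(bool)
        ours = mcc(ConfusionCounts.from_predictions(truth, pred))
        ref = matthews_corrcoef(truth, pred)
        assert ours == pytest.approx(ref, abs=1e-12)


# -- network score ----------------------------------------------------------


def test_rs_net_two_genes_doubles_the_pair_score(table1_task):
    net = rs_net(table1_task, ["G1", "G2"])
    pair = rs_pair(table1_task, "G1", "G2").rs_pair
    assert net == pytest.approx(2.0 * pair, abs=1e-12)


def test_rs_net_constant_subset_is_zero():
    task = _task(np.ones((8, 4)), ["a"] * 4 + ["b"] * 4)
    assert rs_net(task, ["g0", "g1", "g2"]) == 0.0


def test_rs_net_matches_double_loop_oracle(rng, table1_task):
    genes = ["G1", "G2", "G5", "G9", "G10", "G11"]
    got = rs_net(table1_task, genes)
    cols = [table1_task.gene_index(g) for g in genes]
    want = loop_rs_net(table1_task.X[:, cols], table1_task.is_positive)
    assert got == pytest.approx(want, abs=1e-10)
    # random continuous data too
    X = rng.normal(size=(10, 5))
    task = _task(X, ["a"] * 5 + ["b"] * 5)
    got = rs_net(task, task.gene_ids)
    assert got == pytest.approx(
        loop_rs_net(task.X, task.is_positive), abs=1e-10
    )


def test_rs_net_invariant_under_subset_permutation(table1_task):
    a = rs_net(table1_task, ["G1", "G5", "G11"])
    b = rs_net(table1_task, ["G11", "G1", "G5"])
    assert a == pytest.approx(b, abs=1e-12)


def test_rs_net_needs_two_genes(table1_task):
    with pytest.raises(ValueError):
        rs_net(table1_task, ["G1"])


# -- transductive prediction ------------------------------------------------


def test_single_gene_prediction_follows_the_purer_table(table1_task):
    low = dict.fromkeys(table1_task.gene_ids, 0.0) | {"G1": 50.0}
    high = dict.fromkeys(table1_task.gene_ids, 0.0) | {"G1": 100.0}
    assert dc_predict_binary(table1_task, low, ["G1"]).predicted == "+"
    assert dc_predict_binary(table1_task, high, ["G1"]).predicted == "-"


def test_duplicating_a_positive_training_sample_predicts_positive(
    table1_task,
):
    d = table1_task.parent
    sample = dict(zip(d.gene_ids, d.values[0]))
    genes = ["G1", "G2", "G3", "G4"]
    vote = dc_predict_binary(table1_task, sample, genes)
    assert vote.predicted == "+"
    assert vote.rs_net_plus > vote.rs_net_minus


def test_exact_score_tie_goes_to_the_negative_label():
    # a fully symmetric one-gene problem: both assignments give the same
    # merged table, so the strict ">" rule must fall through to "-"
    task = _task(
        np.array([[1.0], [2.0], [1.0], [2.0]]), ["a", "a", "b", "b"]
    )
    vote = dc_predict_binary(task, {"g0": 1.5}, ["g0"])
    assert vote.rs_net_plus == vote.rs_net_minus
    assert vote.predicted == "-"


def test_missing_gene_value_is_an_error(table1_task):
    with pytest.raises(ValueError, match="lacks a value"):
        dc_predict_binary(table1_task, {"G2": 1.0}, ["G1"])


# -- forward selection ------------------------------------------------------


def test_perfect_first_gene_is_selected_alone(table1_task):
    ranking = integrated_rank(table1_task)
    state = forward_select(table1_task, ranking)
    assert state.mcc_benchmark == 1.0
    assert len(state.selected_genes) == 1
    assert state.selected_genes[0] == ranking.ranked_genes[0]
    # nothing can strictly beat an MCC of 1
    assert all(not kept for _, _, kept in state.trace[1:])


def test_benchmark_is_non_decreasing_and_bounded(rng):
    X = rng.normal(size=(14, 10))
    task = _task(X, ["a"] * 7 + ["b"] * 7)
    ranking = integrated_rank(task)
    state = forward_select(task, ranking, B=10)
    benchmarks = [m for _, m, kept in state.trace if kept]
    assert benchmarks == sorted(benchmarks)
    assert -1.0 <= state.mcc_benchmark <= 1.0


def test_scan_bound_limits_candidates(rng):
    X = rng.normal(size=(10, 12))
    task = _task(X, ["a"] * 5 + ["b"] * 5)
    ranking = integrated_rank(task)
    state = forward_select(task, ranking, B=4)
    assert len(state.trace) == 4
    assert set(state.selected_genes) <= set(ranking.ranked_genes[:4])


def test_loocv_decision_equals_held_out_transductive_prediction(rng):
    X = rng.normal(size=(8, 3))
    task = _task(X, ["a"] * 4 + ["b"] * 4)
    be = score_backend("rs")
    genes = list(task.gene_ids)
    inside = _loocv_predictions(task.X, task.is_positive, be)
    for i in range(task.n_samples):
        keep = np.arange(task.n_samples) != i
        rest = task.parent.subset_samples(keep)
        rest_task = BinaryTask(rest, "a", rest.label_mask("a"))
        vote = dc_predict_binary(
            rest_task, dict(zip(task.gene_ids, X[i])), genes
        )
        assert (vote.predicted == "+") == inside[i]


def test_selection_is_deterministic_on_noise(rng):
    X = rng.uniform(size=(12, 8))
    task = _task(X, ["a"] * 6 + ["b"] * 6)
    ranking = integrated_rank(task)
    s1 = forward_select(task, ranking, B=8)
    s2 = forward_select(task, ranking, B=8)
    assert s1.selected_genes == s2.selected_genes
    assert s1.mcc_benchmark == s2.mcc_benchmark
    assert abs(s1.mcc_benchmark) <= 1.0


def test_selection_recovers_planted_genes():
    d = generate(
        SyntheticSpec(
            classes=("C1", "C2"),
            samples_per_class=8,
            planted=(("I", "C1"),),
            n_noise=10,
            seed=3,
        )
    )
    task = binarize(d)[0]
    state = forward_select(task, integrated_rank(task))
    assert state.mcc_benchmark == 1.0
    assert state.selected_genes[0].startswith("p1_I")
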