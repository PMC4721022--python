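"""Transductive direct classification and forward informative-gene selection.

The direct classifier (DC) has no fitted parameters.  To predict a query
sample it assigns each candidate label in turn, merges the relabelled
sample with the training data, recomputes the score of the selected gene
subset on the merged data — endpoints included — and predicts the label
yielding the higher score (ties go to the negative label).  With a single
gene the score is the gene's individual vertical-comparison score; with
two or more it is the network score

    RS_net = sum_{j} sum_{q != j} RS_pair(j, q)

over all ordered pairs of the subset (each unordered pair counted twice).

Gene subsets are grown by forward selection down the integrated ranking:
a candidate gene is kept only if it strictly improves the leave-one-out
cross-validated Matthews correlation coefficient, and the scan stops after
the top ``B`` ranked genes (default 100).  Note the leave-one-out scheme
is itself transductive: the held-out sample is merged back — relabelled —
before scoring, so training statistics always cover all n samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import BinaryTask
from .ranking import GeneRanking
from .contingency import greater_mass
from .scores import ScoreBackend, score_backend

__all__ = [
    "ConfusionCounts",
    "DCVote",
    "SelectionState",
    "mcc",
    "rs_net",
    "dc_predict_binary",
    "forward_select",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        return cls(
            TP=int((truth & predicted).sum()),
            TN=int((~truth & ~predicted).sum()),
            FP=int((~truth & predicted).sum()),
            FN=int((truth & ~predicted).sum()),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fn * fp) / math.sqrt(denom)


@dataclass(frozen=True)
class DCVote:
    """One transductive decision: the score under each assigned label."""

    rs_net_plus: float
    rs_net_minus: float
    predicted_positive: bool
    positive_label: str = "+"
    negative_label: str = "-"

    @property
    def predicted(self) -> str:
        return self.positive_label if self.predicted_positive else self.negative_label


@dataclass
class SelectionState:
    """Outcome of one forward-selection scan."""

    selected_genes: list[str]
    mcc_benchmark: float
    B: int
    trace: list[tuple[str, float, bool]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subset scoring on (possibly relabelled) data
# ---------------------------------------------------------------------------


def _pair_score_sum(
    X: np.ndarray, is_pos: np.ndarray, backend: ScoreBackend
) -> float:
    """Backend pair-score summed over all ordered gene pairs of ``X``.

    Endpoints and all tables are recomputed from ``X`` under the given
    labels.  Returns 0 if either class is empty (no discrimination
    information in a one-class labelling).
    """
    is_pos = np.asarray(is_pos, dtype=bool)
    n_pos = int(is_pos.sum())
    if n_pos == 0 or n_pos == X.shape[0]:
        return 0.0
    ep = (X[is_pos].mean(axis=0) + X[~is_pos].mean(axis=0)) / 2.0
    U = greater_mass(X, ep[None, :])
    r = X.shape[1]

    ver = np.empty((r, r, 2, 4))
    for row, Uc in ((0, U[is_pos]), (1, U[~is_pos])):
        Vc = 1.0 - Uc
        ver[:, :, row, 0] = Uc.T @ Uc
        ver[:, :, row, 1] = Uc.T @ Vc
        ver[:, :, row, 2] = Vc.T @ Uc
        ver[:, :, row, 3] = Vc.T @ Vc

    hor = np.empty((r, r, 2, 2))
    for row, Xc in ((0, X[is_pos]), (1, X[~is_pos])):
        gt = np.zeros((r, r))
        lt = np.zeros((r, r))
        for x in Xc:
            g = (x[:, None] > x[None, :]) + 0.5 * (x[:, None] == x[None, :])
            gt += g
            lt += 1.0 - g
        hor[:, :, row, 0] = gt
        hor[:, :, row, 1] = lt

    pair = np.asarray(backend.pair_arrays(hor, ver), dtype=float)
    np.fill_diagonal(pair, 0.0)
    # ordered (j, q) accumulation, row-major, matching the double loop
    return float(np.cumsum(pair.ravel())[-1])


def _individual_score(
    x: np.ndarray, is_pos: np.ndarray, backend: ScoreBackend
) -> float:
    """Backend individual score of one gene under the given labels."""
    is_pos = np.asarray(is_pos, dtype=bool)
    n_pos = int(is_pos.sum())
    if n_pos == 0 or n_pos == x.shape[0]:
        return 0.0
    ep = (x[is_pos].mean() + x[~is_pos].mean()) / 2.0
    u = greater_mass(x, ep)
    counts = np.array(
        [
            [u[is_pos].sum(), (1.0 - u[is_pos]).sum()],
            [u[~is_pos].sum(), (1.0 - u[~is_pos]).sum()],
        ]
    )
    return float(backend.individual_arrays(counts))


def _subset_score(
    X: np.ndarray, is_pos: np.ndarray, backend: ScoreBackend
) -> float:
    if X.shape[1] == 1:
        return _individual_score(X[:, 0], is_pos, backend)
    return _pair_score_sum(X, is_pos, backend)


def rs_net(
    task: BinaryTask,
    genes: list[str],
    backend: ScoreBackend | str = "rs",
) -> float:
    """Network score of a gene subset on the task's (assigned) labels."""
    if len(genes) < 2:
        raise ValueError("the network score needs at least 2 genes")
    be = score_backend(backend) if isinstance(backend, str) else backend
    cols = [task.gene_index(g) for g in genes]
    return _pair_score_sum(task.X[:, cols], task.is_positive, be)


def dc_predict_binary(
    train: BinaryTask,
    sample,
    genes: list[str],
    backend: ScoreBackend | str = "rs",
    labels: tuple[str, str] = ("+", "-"),
) -> DCVote:
    """Predict one sample by transductive label assignment.

    ``sample`` is either a mapping from gene id to expression value or an
    array aligned with the training dataset's gene order.  The sample is
    merged into the training data under each label in turn; the strictly
    larger score wins and ties go to the negative label.
    """
    if not genes:
        raise ValueError("gene subset must be non-empty")
    be = score_backend(backend) if isinstance(backend, str) else backend
    cols = [train.gene_index(g) for g in genes]
    if isinstance(sample, dict):
        try:
            row = np.array([float(sample[g]) for g in genes])
        except KeyError as e:
            raise ValueError(f"sample lacks a value for gene {e.args[0]!r}") from None
    else:
        sample = np.asarray(sample, dtype=float)
        if sample.shape != (train.parent.n_genes,):
            raise ValueError(
                "sample array must align with the training gene order"
            )
        row = sample[cols]
    X = np.vstack([train.X[:, cols], row])
    base = np.append(train.is_positive, False)
    plus = base.copy()
    plus[-1] = True
    minus = base
    s_plus = _subset_score(X, plus, be)
    s_minus = _subset_score(X, minus, be)
    return DCVote(
        rs_net_plus=s_plus,
        rs_net_minus=s_minus,
        predicted_positive=s_plus > s_minus,
        positive_label=labels[0],
        negative_label=labels[1],
    )


def _loocv_predictions(
    X: np.ndarray, is_pos: np.ndarray, backend: ScoreBackend
) -> np.ndarray:
    """Transductive leave-one-out predictions for every sample.

    Each sample is relabelled + then -, scored on the full merged data,
    and predicted positive only on a strict score win.
    """
    n = X.shape[0]
    pred = np.zeros(n, dtype=bool)
    for i in range(n):
        lab = np.asarray(is_pos, dtype=bool).copy()
        lab[i] = True
        s_plus = _subset_score(X, lab, backend)
        lab[i] = False
        s_minus = _subset_score(X, lab, backend)
        pred[i] = s_plus > s_minus
    return pred


def forward_select(
    task: BinaryTask,
    ranking: GeneRanking,
    B: int = 100,
    backend: ScoreBackend | str = "rs",
) -> SelectionState:
    """Grow a gene subset down the ranking under strict LOOCV-MCC improvement.

    The first-ranked gene sets the benchmark unconditionally; every later
    candidate within the top ``B`` is kept only if the leave-one-out MCC of
    the enlarged subset strictly exceeds the benchmark.
    """
    be = score_backend(backend) if isinstance(backend, str) else backend
    ranked = ranking.ranked_genes
    truth = task.is_positive
    scan = ranked[: min(B, len(ranked))]

    first = scan[0]
    cols = [task.gene_index(first)]
    pred = _loocv_predictions(task.X[:, cols], truth, be)
    benchmark = mcc(ConfusionCounts.from_predictions(truth, pred))
    selected = [first]
    trace = [(first, benchmark, True)]

    for gene in scan[1:]:
        cand = cols + [task.gene_index(gene)]
        pred = _loocv_predictions(task.X[:, cand], truth, be)
        mcc_r = mcc(ConfusionCounts.from_predictions(truth, pred))
        kept = mcc_r > benchmark
        if kept:
            cols = cand
            selected.append(gene)
            benchmark = mcc_r
        trace.append((gene, mcc_r, kept))
    return SelectionState(
        selected_genes=selected,
        mcc_benchmark=benchmark,
        B=B,
        trace=trace,
    )
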