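"""One-vs-rest gene-subset fitting and paired-votes multiclass prediction.

Training runs outlier adjustment once on the multi-class training set,
splits it into m one-vs-rest tasks, ranks genes per task by integrated
score, and forward-selects each task's binary-discriminative informative
gene (BDIG) subset.  Prediction is a sequential class-vs-class
tournament: the first two classes in canonical order contest, the
training data restricted to their samples and to the union of their BDIG
subsets; the transductive direct classifier decides the contest, the
winner meets the next class, and the last winner after m - 1 contests is
the prediction.  This keeps contest sample sizes balanced while needing
only 2m - 1 binary decisions per fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from .preprocess import BinaryTask, PreprocessConfig, adjust_outliers, binarize
from .ranking import GeneRanking, integrated_rank
from .scores import ScoreBackend, score_backend
from .selection import SelectionState, dc_predict_binary, forward_select

__all__ = ["DCModel", "ContestVote", "PredictionResult", "fit", "predict", "evaluate"]


@dataclass(frozen=True)
class ContestVote:
    """One tournament contest between two classes."""

    class_t: str
    class_w: str
    score_t: float
    score_w: float
    winner: str


@dataclass
class DCModel:
    """A fitted direct-classifier model.

    Holds the (outlier-adjusted) training data needed for transductive
    prediction, the canonical class order, and per class its BDIG subset
    with the selection benchmark MCC.
    """

    train: ExpressionDataset
    class_order: list[str]
    bdig: dict[str, list[str]]
    benchmarks: dict[str, float]
    backend: str = "rs"
    B: int = 100
    selection: dict[str, SelectionState] = field(default_factory=dict)
    rankings: dict[str, GeneRanking] = field(default_factory=dict)

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for cls in self.class_order:
            for g in self.bdig[cls]:
                if g not in out:
                    out.append(g)
        return out


@dataclass
class PredictionResult:
    sample_ids: list[str]
    predicted: list[str]
    votes: list[list[ContestVote]]
    true_labels: list[str] | None = None

    @property
    def accuracy(self) -> float:
        if self.true_labels is None:
            raise ValueError("no true labels to score against")
        correct = sum(
            p == t for p, t in zip(self.predicted, self.true_labels)
        )
        return correct / len(self.predicted)


def fit(
    train: ExpressionDataset,
    backend: ScoreBackend | str = "rs",
    B: int = 100,
    preprocess: PreprocessConfig | None = None,
    outlier_adjust: bool = True,
    pair_subset: int | None = None,
) -> DCModel:
    """Fit one BDIG subset per class on an m-class training set."""
    be = score_backend(backend) if isinstance(backend, str) else backend
    for cls in train.classes:
        n_cls = sum(l == cls for l in train.labels)
        if n_cls < 2:
            raise ValueError(
                f"class {cls!r} has {n_cls} sample(s); need at least 2"
            )
    if outlier_adjust:
        adjusted, _ = adjust_outliers(train, preprocess)
    else:
        adjusted = train
    bdig: dict[str, list[str]] = {}
    benchmarks: dict[str, float] = {}
    selections: dict[str, SelectionState] = {}
    rankings: dict[str, GeneRanking] = {}
    for task in binarize(adjusted):
        ranking = integrated_rank(task, be, pair_subset=pair_subset)
        state = forward_select(task, ranking, B=B, backend=be)
        cls = task.positive_class
        bdig[cls] = state.selected_genes
        benchmarks[cls] = state.mcc_benchmark
        selections[cls] = state
        rankings[cls] = ranking
    return DCModel(
        train=adjusted,
        class_order=list(adjusted.classes),
        bdig=bdig,
        benchmarks=benchmarks,
        backend=be.name,
        B=B,
        selection=selections,
        rankings=rankings,
    )


def _contest_genes(model: DCModel, t: str, w: str) -> list[str]:
    genes = list(model.bdig[t])
    for g in model.bdig[w]:
        if g not in genes:
            genes.append(g)
    return genes


def predict(
    model: DCModel, sample: dict[str, float] | np.ndarray
) -> tuple[str, list[ContestVote]]:
    """Predict one sample's class by the paired-votes tournament.

    ``sample`` maps gene ids to expression values (or is an array aligned
    with the training gene order) and must cover every BDIG gene.  In each
    contest the earlier class of the pair plays the positive role; ties go
    to the later class.
    """
    be = score_backend(model.backend)
    if isinstance(sample, np.ndarray):
        sample = dict(zip(model.train.gene_ids, np.asarray(sample, float)))
    missing = [g for g in model.all_genes if g not in sample]
    if missing:
        raise ValueError(f"sample lacks values for BDIG genes: {missing[:5]}")
    order = model.class_order
    current = order[0]
    votes: list[ContestVote] = []
    for challenger in order[1:]:
        genes = _contest_genes(model, current, challenger)
        mask = np.array(
            [l in (current, challenger) for l in model.train.labels]
        )
        contest_train = model.train.subset_samples(mask)
        task = BinaryTask(
            parent=contest_train,
            positive_class=current,
            is_positive=contest_train.label_mask(current),
        )
        vote = dc_predict_binary(
            task,
            {g: sample[g] for g in genes},
            genes,
            backend=be,
            labels=(current, challenger),
        )
        votes.append(
            ContestVote(
                class_t=current,
                class_w=challenger,
                score_t=vote.rs_net_plus,
                score_w=vote.rs_net_minus,
                winner=vote.predicted,
            )
        )
        current = vote.predicted
    return current, votes


def evaluate(model: DCModel, test: ExpressionDataset) -> PredictionResult:
    """Predict every test sample and report accuracy against its labels."""
    missing = [g for g in model.all_genes if g not in test.gene_ids]
    if missing:
        raise ValueError(
            f"test set lacks BDIG genes: {missing[:5]}"
        )
    unseen = sorted(set(test.labels) - set(model.class_order))
    if unseen:
        warnings.warn(
            f"test labels never seen in training (counted as errors): {unseen}",
            stacklevel=2,
        )
    predicted: list[str] = []
    votes: list[list[ContestVote]] = []
    for i, sid in enumerate(test.sample_ids):
        sample = dict(zip(test.gene_ids, test.values[i]))
        cls, v = predict(model, sample)
        predicted.append(cls)
        votes.append(v)
    return PredictionResult(
        sample_ids=list(test.sample_ids),
        predicted=predicted,
        votes=votes,
        true_labels=list(test.labels),
    )
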