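"""Training-set outlier adjustment and one-vs-rest binarization.

Outliers — expression values outside the two-sided normal band
``mean ± u_alpha * sd`` of their gene — overstate class differences and
are pulled back to the edge of the leave-one-out band before any scoring.
Adjustment is a training-set-only step; test samples are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dataset import ExpressionDataset

__all__ = [
    "PreprocessConfig",
    "OutlierAdjustment",
    "OutlierReport",
    "BinaryTask",
    "adjust_outliers",
    "binarize",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the outlier band.

    ``alpha`` is the two-sided significance level; ``u_alpha`` the matching
    standard-normal quantile.  The conventional pairing is alpha = 0.05 with
    u = 1.96; if ``u_alpha`` is left ``None`` it is derived from ``alpha``
    (except at 0.05, where the customary rounded 1.96 is used).  ``sd_ddof``
    selects the sample (1, default) or population (0) standard deviation.
    """

    alpha: float = 0.05
    u_alpha: float | None = None
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")

    @property
    def u(self) -> float:
        if self.u_alpha is not None:
            return self.u_alpha
        if self.alpha == 0.05:
            return 1.96
        return float(norm.ppf(1.0 - self.alpha / 2.0))


@dataclass(frozen=True)
class OutlierAdjustment:
    """One replaced cell: where, what it was, and the statistics used."""

    sample_id: str
    gene_id: str
    sample_index: int
    gene_index: int
    original: float
    gene_mean: float
    gene_sd: float
    loo_mean: float
    loo_sd: float
    replacement: float


@dataclass
class OutlierReport:
    adjustments: list[OutlierAdjustment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.adjustments)

    def __iter__(self):
        return iter(self.adjustments)

    def to_rows(self) -> list[dict]:
        return [vars(a) for a in self.adjustments]


@dataclass
class BinaryTask:
    """A one-vs-rest view of a dataset: one class positive, the rest negative.

    ``is_positive`` is a boolean mask over the parent's samples.  The
    expression matrix is shared with the parent (no copy).
    """

    parent: ExpressionDataset
    positive_class: str
    is_positive: np.ndarray

    def __post_init__(self) -> None:
        self.is_positive = np.asarray(self.is_positive, dtype=bool)
        if self.is_positive.shape != (self.parent.n_samples,):
            raise ValueError("is_positive must mask the parent's samples")
        n_pos = int(self.is_positive.sum())
        if n_pos == 0 or n_pos == self.parent.n_samples:
            raise ValueError(
                f"both classes must be non-empty for task "
                f"{self.positive_class!r}"
            )

    @property
    def X(self) -> np.ndarray:
        return self.parent.values

    @property
    def gene_ids(self) -> list[str]:
        return self.parent.gene_ids

    @property
    def n_samples(self) -> int:
        return self.parent.n_samples

    @property
    def n_positive(self) -> int:
        return int(self.is_positive.sum())

    @property
    def n_negative(self) -> int:
        return self.n_samples - self.n_positive

    def gene_index(self, gene: str) -> int:
        return self.parent.gene_index(gene)


def adjust_outliers(
    dataset: ExpressionDataset,
    config: PreprocessConfig | None = None,
) -> tuple[ExpressionDataset, OutlierReport]:
    """Replace per-gene outliers by the edge of the leave-one-out band.

    For each gene independently, the outlier band is computed once from
    all ``n`` original values.  A cell below ``mean - u*sd`` is replaced by
    ``loo_mean - u*loo_sd`` and a cell above ``mean + u*sd`` by
    ``loo_mean + u*loo_sd``, where the leave-one-out statistics exclude the
    offending cell (single pass, no cascading).  A constant gene has sd 0
    and therefore no outliers.
    """
    config = config or PreprocessConfig()
    n = dataset.n_samples
    if n < 3:
        raise ValueError(
            "outlier adjustment needs at least 3 samples for "
            "leave-one-out statistics"
        )
    u = config.u
    ddof = config.sd_ddof
    X = dataset.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    lower = means - u * sds
    upper = means + u * sds
    out = X.copy()
    report = OutlierReport()
    low_cells = np.argwhere(X < lower)
    high_cells = np.argwhere(X > upper)
    for cells, sign in ((low_cells, -1.0), (high_cells, +1.0)):
        for i, j in cells:
            rest = np.delete(X[:, j], i)
            loo_mean = rest.mean()
            loo_sd = rest.std(ddof=ddof)
            repl = loo_mean + sign * u * loo_sd
            out[i, j] = repl
            report.adjustments.append(
                OutlierAdjustment(
                    sample_id=dataset.sample_ids[i],
                    gene_id=dataset.gene_ids[j],
                    sample_index=int(i),
                    gene_index=int(j),
                    original=float(X[i, j]),
                    gene_mean=float(means[j]),
                    gene_sd=float(sds[j]),
                    loo_mean=float(loo_mean),
                    loo_sd=float(loo_sd),
                    replacement=float(repl),
                )
            )
    report.adjustments.sort(key=lambda a: (a.sample_index, a.gene_index))
    adjusted = ExpressionDataset(
        sample_ids=list(dataset.sample_ids),
        gene_ids=list(dataset.gene_ids),
        values=out,
        labels=list(dataset.labels),
        class_order=list(dataset.classes),
    )
    return adjusted, report


def binarize(dataset: ExpressionDataset) -> list[BinaryTask]:
    """Split an m-class dataset into m one-vs-rest binary tasks.

    Tasks come back in canonical class order; task t has the samples of
    class t as positives and every other sample as negative.
    """
    return [
        BinaryTask(
            parent=dataset,
            positive_class=cls,
            is_positive=dataset.label_mask(cls),
        )
        for cls in dataset.classes
    ]
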