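"""Contingency tables for vertical and horizontal gene evaluation.

Three table shapes feed every score in the package:

* the 2x2 *vertical individual* table — one gene, thresholded at its
  endpoint (midpoint of the two class means), cross-tabulated against
  class;
* the 2x2 *horizontal pair* table — within-sample order relation between
  two genes, per class;
* the 2x4 *vertical pair* table — the joint above/below-endpoint state of
  two genes, per class.

A value exactly on a threshold (or an exact within-sample tie between two
genes) splits its unit mass 0.5/0.5 across the two columns of its class
row, so counts are half-integers; a sample tied on both genes of a
vertical pair splits 0.25 four ways.  Mass is always conserved: every
table's grand total equals the task's sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinaryTask

__all__ = [
    "ContingencyTable",
    "endpoint",
    "individual_table",
    "horizontal_pair_table",
    "vertical_pair_table",
    "greater_mass",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2 x r table of non-negative (possibly half-integer) counts.

    Row 0 is the positive class, row 1 the negative class.  Column order
    is fixed: column 1 is the ">" outcome (and for 2x4 tables the order is
    (>,>), (>,<), (<,>), (<,<)).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 2:
            raise ValueError(f"expected a 2 x r table, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def r(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


def endpoint(task: BinaryTask, gene: str) -> float:
    """Binarization threshold for a gene: midpoint of the two class means."""
    x = task.parent.gene_values(gene)
    return _endpoint_from_values(x, task.is_positive)


def _endpoint_from_values(x: np.ndarray, is_pos: np.ndarray) -> float:
    return float((x[~is_pos].mean() + x[is_pos].mean()) / 2.0)


def greater_mass(x: np.ndarray, threshold: float | np.ndarray) -> np.ndarray:
    """Per-sample mass assigned to the ">" side: 1 above, 0 below, 0.5 on a tie."""
    x = np.asarray(x, dtype=float)
    return (x > threshold) + 0.5 * (x == threshold)


def individual_table(
    task: BinaryTask, gene: str, ep: float | None = None
) -> ContingencyTable:
    """2x2 vertical table of one gene: columns (> EP, < EP), rows (+, -)."""
    x = task.parent.gene_values(gene)
    if ep is None:
        ep = _endpoint_from_values(x, task.is_positive)
    u = greater_mass(x, ep)
    pos, neg = task.is_positive, ~task.is_positive
    counts = np.array(
        [
            [u[pos].sum(), (1.0 - u[pos]).sum()],
            [u[neg].sum(), (1.0 - u[neg]).sum()],
        ]
    )
    return ContingencyTable(counts)


def horizontal_pair_table(
    task: BinaryTask, gene_j: str, gene_q: str
) -> ContingencyTable:
    """2x2 horizontal table: columns (X_j > X_q, X_j < X_q), rows (+, -)."""
    if gene_j == gene_q:
        raise ValueError("horizontal comparison needs two distinct genes")
    xj = task.parent.gene_values(gene_j)
    xq = task.parent.gene_values(gene_q)
    h = greater_mass(xj, xq)
    pos, neg = task.is_positive, ~task.is_positive
    counts = np.array(
        [
            [h[pos].sum(), (1.0 - h[pos]).sum()],
            [h[neg].sum(), (1.0 - h[neg]).sum()],
        ]
    )
    return ContingencyTable(counts)


def vertical_pair_table(
    task: BinaryTask,
    gene_j: str,
    gene_q: str,
    ep_j: float | None = None,
    ep_q: float | None = None,
) -> ContingencyTable:
    """2x4 vertical table over columns (>,>), (>,<), (<,>), (<,<).

    A tie on one gene splits the sample 0.5/0.5 across the two columns
    consistent with the other gene; a tie on both splits 0.25 four ways
    (the two splits are independent).
    """
    if gene_j == gene_q:
        raise ValueError("vertical pair comparison needs two distinct genes")
    xj = task.parent.gene_values(gene_j)
    xq = task.parent.gene_values(gene_q)
    if ep_j is None:
        ep_j = _endpoint_from_values(xj, task.is_positive)
    if ep_q is None:
        ep_q = _endpoint_from_values(xq, task.is_positive)
    uj = greater_mass(xj, ep_j)
    uq = greater_mass(xq, ep_q)
    rows = []
    for mask in (task.is_positive, ~task.is_positive):
        a, b = uj[mask], uq[mask]
        rows.append(
            [
                (a * b).sum(),
                (a * (1.0 - b)).sum(),
                ((1.0 - a) * b).sum(),
                ((1.0 - a) * (1.0 - b)).sum(),
            ]
        )
    return ContingencyTable(np.array(rows))
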