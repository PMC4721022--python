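"""Labeled expression-matrix data model and delimited-text I/O.

The universal input of the package is a continuous expression matrix of
``n`` samples by ``p`` genes together with one categorical class label per
sample.  In memory the canonical orientation is samples as rows and genes
as columns; files in either orientation are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
]


class DatasetFormatError(ValueError):
    """The file cannot be interpreted as a labeled expression matrix."""


class DatasetValidationError(ValueError):
    """The parsed matrix violates a dataset invariant."""


@dataclass
class ExpressionDataset:
    """An ``n x p`` expression matrix with one class label per sample.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, length ``n``.
    gene_ids
        Unique gene identifiers, length ``p``.
    values
        Float matrix of shape ``(n, p)``, arbitrary expression units,
        no missing values.
    labels
        Class label per sample; at least two distinct classes, each
        occurring at least once.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: list[str]
    class_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        if self.class_order is None:
            self.class_order = list(dict.fromkeys(self.labels))
        self._validate()

    # -- invariants -----------------------------------------------------
    def _validate(self) -> None:
        n, p = self.n_samples, self.n_genes
        if self.values.ndim != 2 or self.values.shape != (n, p):
            raise DatasetValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {p} genes"
            )
        if n < 2:
            raise DatasetValidationError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise DatasetValidationError("need at least 1 gene")
        if len(self.labels) != n:
            raise DatasetValidationError("one label required per sample")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise DatasetValidationError(f"duplicate sample ids: {dupes}")
        if len(set(self.gene_ids)) != p:
            dupes = _duplicates(self.gene_ids)
            raise DatasetValidationError(f"duplicate gene ids: {dupes}")
        if self.n_classes < 2:
            raise DatasetValidationError(
                f"need at least 2 classes, got {sorted(set(self.labels))}"
            )
        if set(self.class_order) != set(self.labels):
            raise DatasetValidationError(
                "class_order must list exactly the observed classes"
            )
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            coords = [
                (self.sample_ids[i], self.gene_ids[j]) for i, j in bad[:10]
            ]
            raise DatasetValidationError(
                f"non-finite expression values at (sample, gene): {coords}"
            )

    # -- accessors ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def classes(self) -> list[str]:
        """Canonical class order (first appearance unless overridden)."""
        return list(self.class_order)

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def label_mask(self, cls: str) -> np.ndarray:
        return np.array([l == cls for l in self.labels], dtype=bool)

    def subset_samples(self, mask: np.ndarray) -> "ExpressionDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            values=self.values[idx],
            labels=[self.labels[i] for i in idx],
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        if label_column in self.gene_ids:
            raise DatasetValidationError(
                f"label column {label_column!r} collides with a gene id"
            )
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.gene_ids
        )
        df.insert(0, label_column, self.labels)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(
    path: str | Path,
    orientation: str = "samples-as-rows",
    label_column: str = "class",
    class_order: list[str] | None = None,
) -> ExpressionDataset:
    """Read a labeled expression matrix from delimited text.

    The delimiter is chosen from the extension (``.tsv``/``.tab``/``.txt``
    are tab separated, anything else comma separated).  With
    ``orientation="samples-as-rows"`` the first column holds sample ids,
    the header holds gene ids plus the label column.  With
    ``orientation="genes-as-rows"`` the layout is transposed: the header
    holds sample ids, the first column gene ids, and one row whose id
    equals ``label_column`` carries the class labels.
    """
    path = Path(path)
    if orientation not in {"samples-as-rows", "genes-as-rows"}:
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if orientation == "genes-as-rows":
        df = df.T
    if label_column not in df.columns:
        raise DatasetFormatError(
            f"label column {label_column!r} not found in {path}"
        )
    labels = df[label_column].astype(str).tolist()
    expr = df.drop(columns=[label_column])
    values = np.empty(expr.shape, dtype=float)
    bad: list[tuple[str, str]] = []
    for j, col in enumerate(expr.columns):
        raw = expr[col].to_numpy(dtype=object)
        try:
            # correctly-rounded string conversion (full precision survives
            # a write/read cycle bit for bit)
            converted = raw.astype(np.float64)
        except (TypeError, ValueError):
            converted = np.empty(len(raw))
            for i, cell in enumerate(raw):
                try:
                    converted[i] = float(cell)
                except (TypeError, ValueError):
                    converted[i] = np.nan
        finite = np.isfinite(converted)
        bad.extend(
            (str(expr.index[i]), str(col))
            for i in np.flatnonzero(~finite)
        )
        values[:, j] = converted
    if bad:
        raise DatasetValidationError(
            f"non-numeric or missing expression values at "
            f"(sample, gene): {bad[:10]}"
        )
    return ExpressionDataset(
        sample_ids=[str(s) for s in expr.index],
        gene_ids=[str(g) for g in expr.columns],
        values=values,
        labels=labels,
        class_order=class_order,
    )


def write_dataset(
    dataset: ExpressionDataset,
    path: str | Path,
    label_column: str = "class",
) -> None:
    """Write a dataset as delimited text (samples as rows, full precision).

    Values are serialised with :func:`repr`-level precision so that
    ``read_dataset(write_dataset(d)) == d`` exactly.
    """
    path = Path(path)
    df = dataset.to_frame(label_column)
    # repr round-trips float64 exactly; pandas' default float_format does too
    df.to_csv(path, sep=_sep_for(path), index_label="sample")
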