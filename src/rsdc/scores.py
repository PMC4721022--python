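"""Entropy, complexity, relative simplicity and chi-square scores.

Complexity of a 2 x r contingency table is an entropy-like quantity that
keeps absolute frequencies instead of probabilities:

    C_row    = - sum_d f+d log2(f+d / f+)  -  sum_d f-d log2(f-d / f-)
    C_column = - sum_d [ f+d log2(f+d / fd) + f-d log2(f-d / fd) ]
    C        = C_row + C_column

The maximum complexity belongs to the table with the same margins whose
columns are equal within each class row:

    C_row-max    = n log2(r)
    C_column-max = - f+ log2(f+ / n) - f- log2(f- / n)

Relative simplicity normalises the complexity deficit,
``RS = (C_max - C) / C_max``: 1 for a perfectly class-separating table,
0 for a maximally complex one.  Unlike Shannon entropy, C and C_max grow
with absolute counts, so RS sees sample size, not only ratios.

Two chi-square statistics accompany RS as comparator scores: a 2x2
statistic with Yates' continuity correction *without* flooring the
corrected term at zero (the variant whose values the simulation and the
worked real-data tables reproduce), and the plain Pearson statistic for
2x4 tables.

All scalar scores delegate to array kernels that accept stacked count
arrays of shape ``(..., 2, r)``; the gene-ranking module calls the kernels
directly on p x p pair matrices.  Sums over table cells accumulate in a
fixed order (positive row left-to-right, then negative row; for column
terms, + above - within each column left-to-right) so results are
bit-reproducible against a literal loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .contingency import ContingencyTable

__all__ = [
    "entropy",
    "complexity",
    "max_complexity",
    "relative_simplicity",
    "chi2_2x2_corrected",
    "chi2_2xr_pearson",
    "chi2_auto",
    "score_backend",
    "score_table",
    "ScoreResult",
    "ScoreBackend",
    "Complexity",
    "MaxComplexity",
    "Chi2Result",
]


class Complexity(NamedTuple):
    C_row: float
    C_column: float
    C: float


class MaxComplexity(NamedTuple):
    C_row_max: float
    C_column_max: float
    C_max: float


class Chi2Result(NamedTuple):
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class ScoreResult:
    """Every score of one table, in bits where dimensional."""

    H: float
    C_row: float
    C_column: float
    C: float
    C_row_max: float
    C_column_max: float
    C_max: float
    RS: float
    chi_square: float
    p_value: float


# ---------------------------------------------------------------------------
# array kernels: counts have shape (..., 2, r)
# ---------------------------------------------------------------------------


def _nlogp(n: np.ndarray, total: np.ndarray) -> np.ndarray:
    """-n * log2(n / total), with the 0 * log 0 convention (term -> 0)."""
    n = np.asarray(n, dtype=float)
    total = np.asarray(total, dtype=float)
    safe_n = np.where(n > 0, n, 1.0)
    safe_t = np.where(total > 0, total, 1.0)
    return np.where(n > 0, -safe_n * np.log2(safe_n / safe_t), 0.0)


def _complexity_arrays(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(C_row, C_column, C) for stacked tables of shape (..., 2, r)."""
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[-1]
    row_tot = counts.sum(axis=-1)  # (..., 2)
    col_tot = counts.sum(axis=-2)  # (..., r)
    # fixed accumulation order: + row columns, then - row columns
    c_row = np.zeros(counts.shape[:-2])
    for i in (0, 1):
        for d in range(r):
            c_row = c_row + _nlogp(counts[..., i, d], row_tot[..., i])
    # columns left-to-right, + above - within each column
    c_col = np.zeros(counts.shape[:-2])
    for d in range(r):
        for i in (0, 1):
            c_col = c_col + _nlogp(counts[..., i, d], col_tot[..., d])
    return c_row, c_col, c_row + c_col


def _max_complexity_arrays(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[-1]
    row_tot = counts.sum(axis=-1)
    n = row_tot[..., 0] + row_tot[..., 1]
    c_row_max = n * np.log2(r)
    c_col_max = _nlogp(row_tot[..., 0], n) + _nlogp(row_tot[..., 1], n)
    return c_row_max, c_col_max, c_row_max + c_col_max


def _rs_arrays(counts: np.ndarray) -> np.ndarray:
    """RS of stacked tables; defined as 0 where C_max is 0."""
    _, _, c = _complexity_arrays(counts)
    _, _, c_max = _max_complexity_arrays(counts)
    safe = np.where(c_max > 0, c_max, 1.0)
    return np.where(c_max > 0, (c_max - c) / safe, 0.0)


def _entropy_decomposition_arrays(
    counts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(H, H_max) of the same row+column decomposition as complexity.

    Every frequency-weighted term of C is replaced by its
    probability-weighted Shannon term; the maximum mirrors the
    equal-column table (each non-empty row uniform over r columns, each
    column distributed like the class margin).
    """
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[-1]
    row_tot = counts.sum(axis=-1)
    col_tot = counts.sum(axis=-2)
    n = row_tot[..., 0] + row_tot[..., 1]

    h_row = np.zeros(counts.shape[:-2])
    for i in (0, 1):
        for d in range(r):
            h_row = h_row + _nlogp(
                _ratio(counts[..., i, d], row_tot[..., i]), 1.0
            )
    h_col = np.zeros(counts.shape[:-2])
    for d in range(r):
        for i in (0, 1):
            h_col = h_col + _nlogp(
                _ratio(counts[..., i, d], col_tot[..., d]), 1.0
            )
    h = h_row + h_col

    h_row_max = (
        np.where(row_tot[..., 0] > 0, np.log2(r), 0.0)
        + np.where(row_tot[..., 1] > 0, np.log2(r), 0.0)
    )
    h_class = _nlogp(_ratio(row_tot[..., 0], n), 1.0) + _nlogp(
        _ratio(row_tot[..., 1], n), 1.0
    )
    n_nonempty_cols = (col_tot > 0).sum(axis=-1)
    h_col_max = n_nonempty_cols * h_class
    return h, h_row_max + h_col_max


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    return np.asarray(num, dtype=float) / np.where(den > 0, den, 1.0)


def _entropy_score_arrays(counts: np.ndarray) -> np.ndarray:
    h, h_max = _entropy_decomposition_arrays(counts)
    safe = np.where(h_max > 0, h_max, 1.0)
    return np.where(h_max > 0, (h_max - h) / safe, 0.0)


def _chi2_2x2_arrays(
    counts: np.ndarray, correction: str = "yates_nofloor"
) -> np.ndarray:
    """2x2 chi-square statistic for stacked tables of shape (..., 2, 2).

    ``yates_nofloor`` (default) subtracts n/2 from \\|ad - bc\\| before
    squaring without flooring at zero; ``yates`` floors; ``none`` is the
    uncorrected Pearson form.  Any zero margin yields 0.
    """
    counts = np.asarray(counts, dtype=float)
    a, b = counts[..., 0, 0], counts[..., 0, 1]
    c, d = counts[..., 1, 0], counts[..., 1, 1]
    n = a + b + c + d
    f1, f2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = f1 * f2 * c1 * c2
    cross = np.abs(a * d - b * c)
    if correction == "yates_nofloor":
        term = cross - n / 2.0
    elif correction == "yates":
        term = np.maximum(cross - n / 2.0, 0.0)
    elif correction == "none":
        term = cross
    else:
        raise ValueError(f"unknown chi2 correction: {correction!r}")
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, n * term**2 / safe, 0.0)


def _chi2_pearson_arrays(counts: np.ndarray) -> np.ndarray:
    """Pearson statistic for stacked 2 x r tables; empty cells with E = 0 skip."""
    counts = np.asarray(counts, dtype=float)
    row_tot = counts.sum(axis=-1, keepdims=True)
    col_tot = counts.sum(axis=-2, keepdims=True)
    n = counts.sum(axis=(-1, -2), keepdims=True)
    expected = row_tot * col_tot / np.where(n > 0, n, 1.0)
    safe = np.where(expected > 0, expected, 1.0)
    terms = np.where(expected > 0, (counts - expected) ** 2 / safe, 0.0)
    return terms.sum(axis=(-1, -2))


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------


def entropy(counts) -> float:
    """Shannon entropy (bits) of a frequency vector; scale-invariant."""
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy needs at least one positive count")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def complexity(table: ContingencyTable) -> Complexity:
    """Row, column and total complexity of a 2 x r table (bits)."""
    c_row, c_col, c = _complexity_arrays(table.counts)
    return Complexity(float(c_row), float(c_col), float(c))


def max_complexity(table: ContingencyTable) -> MaxComplexity:
    """Complexity of the equal-column table with the same margins (bits)."""
    c_row, c_col, c = _max_complexity_arrays(table.counts)
    return MaxComplexity(float(c_row), float(c_col), float(c))


def relative_simplicity(table: ContingencyTable) -> float:
    """(C_max - C) / C_max, in [0, 1]; 0 for the degenerate C_max = 0."""
    return float(_rs_arrays(table.counts))


def chi2_2x2_corrected(
    table: ContingencyTable, correction: str = "yates_nofloor"
) -> Chi2Result:
    """Continuity-corrected 2x2 chi-square (df 1) and its upper-tail p."""
    if table.r != 2:
        raise ValueError(f"2x2 statistic needs r = 2, got r = {table.r}")
    stat = float(_chi2_2x2_arrays(table.counts, correction))
    return Chi2Result(stat, float(_chi2_dist.sf(stat, 1)))


def chi2_2xr_pearson(table: ContingencyTable) -> Chi2Result:
    """Plain Pearson chi-square of a 2 x r table, df r - 1."""
    if table.r < 2:
        raise ValueError("Pearson statistic needs r >= 2")
    stat = float(_chi2_pearson_arrays(table.counts))
    df = table.r - 1
    return Chi2Result(stat, float(_chi2_dist.sf(stat, df)))


def score_table(table: ContingencyTable) -> ScoreResult:
    """All scores of one table bundled together."""
    c = complexity(table)
    cm = max_complexity(table)
    if table.r == 2:
        chi = chi2_2x2_corrected(table)
    else:
        chi = chi2_2xr_pearson(table)
    return ScoreResult(
        H=entropy(table.counts),
        C_row=c.C_row,
        C_column=c.C_column,
        C=c.C,
        C_row_max=cm.C_row_max,
        C_column_max=cm.C_column_max,
        C_max=cm.C_max,
        RS=relative_simplicity(table),
        chi_square=chi.chi_square,
        p_value=chi.p_value,
    )


# ---------------------------------------------------------------------------
# score backends
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreBackend:
    """A drop-in scoring rule over contingency tables.

    ``individual_arrays`` maps stacked 2x2 tables to scores;
    ``pair_arrays`` maps a (horizontal 2x2, vertical 2x4) pair of stacks to
    joint pair scores.  The scalar convenience methods wrap single tables.
    """

    name: str
    individual_arrays: Callable[[np.ndarray], np.ndarray]
    pair_arrays: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def individual(self, table: ContingencyTable) -> float:
        return float(self.individual_arrays(table.counts))

    def pair(self, hor: ContingencyTable, ver: ContingencyTable) -> float:
        return float(self.pair_arrays(hor.counts, ver.counts))

    def __call__(self, table: ContingencyTable) -> float:
        return self.individual(table)


def _rs_pair_arrays(hor: np.ndarray, ver: np.ndarray) -> np.ndarray:
    """Joint pair RS: complexity deficits of both tables pooled before
    normalising, ((C_hmax + C_vmax) - (C_h + C_v)) / (C_hmax + C_vmax)."""
    _, _, c_h = _complexity_arrays(hor)
    _, _, c_hm = _max_complexity_arrays(hor)
    _, _, c_v = _complexity_arrays(ver)
    _, _, c_vm = _max_complexity_arrays(ver)
    c_max = c_hm + c_vm
    safe = np.where(c_max > 0, c_max, 1.0)
    return np.where(c_max > 0, (c_max - (c_h + c_v)) / safe, 0.0)


def _entropy_pair_arrays(hor: np.ndarray, ver: np.ndarray) -> np.ndarray:
    h_h, hm_h = _entropy_decomposition_arrays(hor)
    h_v, hm_v = _entropy_decomposition_arrays(ver)
    h_max = hm_h + hm_v
    safe = np.where(h_max > 0, h_max, 1.0)
    return np.where(h_max > 0, (h_max - (h_h + h_v)) / safe, 0.0)


def _chi2_auto_arrays(
    counts: np.ndarray, correction: str = "yates_nofloor"
) -> np.ndarray:
    """Chi-square with all-empty columns dropped first.

    A 2 x r table whose non-empty columns number exactly two is scored
    with the continuity-corrected 2x2 formula on those columns; wider
    tables take the plain Pearson statistic (which ignores empty columns
    anyway); fewer than two non-empty columns give 0.  This is the rule
    under which one statistic reproduces every simulation-table value:
    sparse two-state pair tables behave exactly like the individual-gene
    2x2 case.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] == 2:
        return _chi2_2x2_arrays(counts, correction)
    col_tot = counts.sum(axis=-2)  # (..., r)
    nonzero = col_tot > 0
    k = nonzero.sum(axis=-1)
    # gather the first two non-empty columns; for k == 2 these are exactly
    # the occupied ones, and the corrected statistic ignores their order
    idx = np.argsort(~nonzero, axis=-1, kind="stable")[..., :2]
    top2 = np.take_along_axis(
        counts, idx[..., None, :].repeat(2, axis=-2), axis=-1
    )
    stat2 = _chi2_2x2_arrays(top2, correction)
    statr = _chi2_pearson_arrays(counts)
    return np.where(k < 2, 0.0, np.where(k == 2, stat2, statr))


def _chi2_individual_arrays(counts: np.ndarray) -> np.ndarray:
    return _chi2_auto_arrays(counts)


def _chi2_pair_arrays(hor: np.ndarray, ver: np.ndarray) -> np.ndarray:
    return _chi2_2x2_arrays(hor) + _chi2_auto_arrays(ver)


def chi2_auto(
    table: ContingencyTable, correction: str = "yates_nofloor"
) -> Chi2Result:
    """Chi-square of any 2 x r table under the empty-column-drop rule.

    Degrees of freedom follow the reduced width (non-empty columns - 1,
    at least 1), so sparse pair tables are judged on the comparisons they
    actually make.
    """
    stat = float(_chi2_auto_arrays(table.counts, correction))
    k = int((table.counts.sum(axis=0) > 0).sum())
    df = max(k - 1, 1)
    return Chi2Result(stat, float(_chi2_dist.sf(stat, df)))


_BACKENDS: dict[str, ScoreBackend] = {
    "rs": ScoreBackend("rs", _rs_arrays, _rs_pair_arrays),
    "entropy": ScoreBackend(
        "entropy", _entropy_score_arrays, _entropy_pair_arrays
    ),
    "chi2": ScoreBackend("chi2", _chi2_individual_arrays, _chi2_pair_arrays),
}


def score_backend(
    name: str, chi2_correction: str = "yates_nofloor"
) -> ScoreBackend:
    """Look up a scoring rule: ``rs`` (default), ``entropy`` or ``chi2``.

    ``chi2_correction`` selects the 2x2 continuity-correction variant used
    by the chi2 backend (``yates_nofloor``, ``yates`` or ``none``).
    """
    if name == "chi2" and chi2_correction != "yates_nofloor":

        def _ind(counts: np.ndarray) -> np.ndarray:
            if counts.shape[-1] == 2:
                return _chi2_2x2_arrays(counts, chi2_correction)
            return _chi2_pearson_arrays(counts)

        def _pair(hor: np.ndarray, ver: np.ndarray) -> np.ndarray:
            return _chi2_2x2_arrays(hor, chi2_correction) + _chi2_pearson_arrays(ver)

        return ScoreBackend("chi2", _ind, _pair)
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown score backend {name!r}; choose from "
            f"{sorted(_BACKENDS)}"
        ) from None
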