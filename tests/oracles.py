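"""Independent brute-force oracles for the tests.

Everything here is a literal, loop-based evaluation of the defining
formulas — tables built sample by sample, complexities accumulated cell
by cell — kept deliberately naive and separate from the package's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np


# -- table construction -----------------------------------------------------


def loop_endpoint(x, is_pos) -> float:
    pos_sum, n_pos = 0.0, 0
    neg_sum, n_neg = 0.0, 0
    for i in range(len(x)):
        if is_pos[i]:
            pos_sum += x[i]
            n_pos += 1
        else:
            neg_sum += x[i]
            n_neg += 1
    return (neg_sum / n_neg + pos_sum / n_pos) / 2.0


def loop_individual_table(x, is_pos, ep) -> np.ndarray:
    t = np.zeros((2, 2))
    for i in range(len(x)):
        row = 0 if is_pos[i] else 1
        if x[i] > ep:
            t[row, 0] += 1.0
        elif x[i] < ep:
            t[row, 1] += 1.0
        else:
            t[row, 0] += 0.5
            t[row, 1] += 0.5
    return t


def loop_horizontal_table(xj, xq, is_pos) -> np.ndarray:
    t = np.zeros((2, 2))
    for i in range(len(xj)):
        row = 0 if is_pos[i] else 1
        if xj[i] > xq[i]:
            t[row, 0] += 1.0
        elif xj[i] < xq[i]:
            t[row, 1] += 1.0
        else:
            t[row, 0] += 0.5
            t[row, 1] += 0.5
    return t


def loop_vertical_pair_table(xj, xq, is_pos, ep_j, ep_q) -> np.ndarray:
    t = np.zeros((2, 4))
    for i in range(len(xj)):
        row = 0 if is_pos[i] else 1
        wj = 1.0 if xj[i] > ep_j else (0.0 if xj[i] < ep_j else 0.5)
        wq = 1.0 if xq[i] > ep_q else (0.0 if xq[i] < ep_q else 0.5)
        t[row, 0] += wj * wq
        t[row, 1] += wj * (1.0 - wq)
        t[row, 2] += (1.0 - wj) * wq
        t[row, 3] += (1.0 - wj) * (1.0 - wq)
    return t


# -- scores -----------------------------------------------------------------


def _term(count: float, total: float) -> float:
    if count > 0:
        return -count * np.log2(count / total)
    return 0.0


def loop_complexity(counts) -> tuple[float, float, float]:
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[1]
    f_pos = counts[0].sum()
    f_neg = counts[1].sum()
    col = counts.sum(axis=0)
    c_row = 0.0
    for d in range(r):
        c_row = c_row + _term(counts[0, d], f_pos)
    for d in range(r):
        c_row = c_row + _term(counts[1, d], f_neg)
    c_col = 0.0
    for d in range(r):
        c_col = c_col + _term(counts[0, d], col[d])
        c_col = c_col + _term(counts[1, d], col[d])
    return c_row, c_col, c_row + c_col


def loop_max_complexity(counts) -> tuple[float, float, float]:
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[1]
    f_pos = counts[0].sum()
    f_neg = counts[1].sum()
    n = f_pos + f_neg
    c_row_max = n * np.log2(r)
    c_col_max = _term(f_pos, n) + _term(f_neg, n)
    return c_row_max, c_col_max, c_row_max + c_col_max


def loop_rs(counts) -> float:
    _, _, c = loop_complexity(counts)
    _, _, c_max = loop_max_complexity(counts)
    if c_max > 0:
        return (c_max - c) / c_max
    return 0.0


def loop_pair_rs(hor_counts, ver_counts) -> float:
    _, _, c_h = loop_complexity(hor_counts)
    _, _, c_hm = loop_max_complexity(hor_counts)
    _, _, c_v = loop_complexity(ver_counts)
    _, _, c_vm = loop_max_complexity(ver_counts)
    c_max = c_hm + c_vm
    if c_max > 0:
        return (c_max - (c_h + c_v)) / c_max
    return 0.0


def loop_pair_rs_from_data(X, is_pos, j, q) -> float:
    ep_j = loop_endpoint(X[:, j], is_pos)
    ep_q = loop_endpoint(X[:, q], is_pos)
    hor = loop_horizontal_table(X[:, j], X[:, q], is_pos)
    ver = loop_vertical_pair_table(X[:, j], X[:, q], is_pos, ep_j, ep_q)
    return loop_pair_rs(hor, ver)


# -- integrated ranking -----------------------------------------------------


def loop_integrated_scores(X, is_pos) -> tuple[np.ndarray, np.ndarray]:
    """Individual RS and integrated RS of every gene by plain double loop."""
    n, p = X.shape
    ind = np.zeros(p)
    for j in range(p):
        ep = loop_endpoint(X[:, j], is_pos)
        ind[j] = loop_rs(loop_individual_table(X[:, j], is_pos, ep))
    pair = np.zeros((p, p))
    for j in range(p):
        for q in range(p):
            if q != j:
                pair[j, q] = loop_pair_rs_from_data(X, is_pos, j, q)
    irs = ind.copy()
    for j in range(p):
        for q in range(p):
            if q == j:
                continue
            denom = ind[j] + ind[q]
            w = ind[j] / denom if denom > 0 else 0.0
            irs[j] = irs[j] + w * pair[j, q]
    return ind, irs


def loop_rs_net(X, is_pos) -> float:
    """Network score: pair RS summed over all ordered gene pairs."""
    p = X.shape[1]
    total = 0.0
    for j in range(p):
        for q in range(p):
            if q != j:
                total = total + loop_pair_rs_from_data(X, is_pos, j, q)
    return total


# -- preprocessing ----------------------------------------------------------


def loop_adjust_outliers(X, u, ddof=1) -> np.ndarray:
    """Literal per-cell outlier replacement, bounds from the original data."""
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n, p = X.shape
    for j in range(p):
        col = X[:, j]
        mean = col.mean()
        sd = col.std(ddof=ddof)
        for i in range(n):
            rest = np.delete(col, i)
            if X[i, j] < mean - u * sd:
                out[i, j] = rest.mean() - u * rest.std(ddof=ddof)
            elif X[i, j] > mean + u * sd:
                out[i, j] = rest.mean() + u * rest.std(ddof=ddof)
    return out


def loop_mcc(tp, tn, fp, fn) -> float:
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fn * fp) / np.sqrt(denom)
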