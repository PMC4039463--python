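"""Small statistical utilities shared across pipeline stages."""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log probability of an r x c table under fixed margins
    (multivariate hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
          - lgamma(n + 1) - sum(lgamma(x + 1) for x in table.flat))
    return lp


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def rec(i: int, remaining_cols: np.ndarray, rows_acc: list):
        if i == r - 1:
            yield rows_acc + [remaining_cols.copy()]
            return
        target = rows[i]
        ranges = [range(min(target, remaining_cols[j]) + 1) for j in range(c - 1)]
        for head in product(*ranges):
            s = sum(head)
            if s > target:
                continue
            last = target - s
            if last > remaining_cols[c - 1]:
                continue
            row = np.array(list(head) + [last])
            yield from rec(i + 1, remaining_cols - row, rows_acc + [row])

    yield from rec(0, cols.astype(int).copy(), [])


def fisher_exact_rxc(table, seed: int | None = None, max_exact_total: int = 60,
                     n_montecarlo: int = 20_000) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    Exhaustively enumerates all tables with the observed margins when the
    grand total is at most ``max_exact_total`` (two-sided p = total
    probability of tables no more likely than the observed one); otherwise a
    seeded Monte-Carlo estimate over random tables with fixed margins.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a non-negative 2-D array")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    lp_obs = _log_table_prob(table)
    tol = 1e-10
    if table.sum() <= max_exact_total:
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _log_table_prob(np.asarray(t))
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return min(p, 1.0)
    rng = np.random.default_rng(seed)
    # sample tables by permuting individual memberships
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_montecarlo):
        perm = rng.permutation(col_labels)
        t = np.zeros_like(table)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t) <= lp_obs + tol:
            hits += 1
    return (hits + 1) / (n_montecarlo + 1)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
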