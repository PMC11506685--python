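"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (enumeration, direct
formulas, BFS path counting) and deliberately shares no code with the
package's computation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist


def bf_chi2_independence(table: np.ndarray) -> tuple[float, float]:
    """Chi-square test of independence from the textbook formula."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stat), float(chi2_dist.sf(stat, dof))


def bf_fisher_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full enumeration of the margin-fixed tables."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def bf_haldane_or(young: np.ndarray, old: np.ndarray) -> float:
    """Odds of first-dominance in old over young, +0.5 on all cells if any zero."""
    a, b = float(old[0]), float(old[1])
    c, d = float(young[0]), float(young[1])
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def bf_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return np.clip(adj, 0, 1)


def bf_pearson(x, y) -> tuple[float, float]:
    """Pearson r from covariance/stddevs and its two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * t_dist.sf(abs(t), n - 2))


def bf_quantile(values, q: float) -> float:
    """Quantile by linear interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def bf_betweenness(edges, nodes) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration (BFS)."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    btw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # BFS all shortest paths s -> t
        paths = []
        frontier = [[s]]
        found_len = None
        while frontier and found_len is None:
            nxt = []
            for path in frontier:
                for nb in adj[path[-1]]:
                    if nb in path:
                        continue
                    new = path + [nb]
                    if nb == t:
                        paths.append(new)
                    else:
                        nxt.append(new)
            if paths:
                found_len = len(paths[0])
            frontier = nxt
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        paths = [p for p in paths if len(p) == shortest]
        for p in paths:
            for interior in p[1:-1]:
                btw[interior] += 1.0 / len(paths)
    return btw


def bf_ssgsea(order: list[str], members: set[str], alpha: float) -> float:
    """ssGSEA running-sum score computed step by step from the definition."""
    n = len(order)
    weights = [(n - i) ** alpha for i in range(n)]  # position i (0-based): rank weight n-i
    denom = sum(w for w, g in zip(weights, order) if g in members)
    rs = 0.0
    total = 0.0
    for i, g in enumerate(order):
        if g in members:
            rs += weights[i] / denom
        else:
            rs -= 1.0 / (n - len(members))
        total += rs
    return total
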