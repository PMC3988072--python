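"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
library routines) used by the package itself: betweenness is computed
by explicit enumeration of all shortest paths, the t-test and Pearson
correlation from textbook formulas, and the log-log regression from the
closed-form normal equations.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy import stats as sps


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Normalized BC by enumerating every shortest path between every
    unordered node pair."""
    n = g.number_of_nodes()
    nodes = list(g.nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for s, t in itertools.combinations(nodes, 2):
        if t not in lengths[s]:
            continue
        d = lengths[s][t]
        paths = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) - 1 == d
        ]
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2
    return {v: x / norm for v, x in bc.items()}


def textbook_ttest(case, ctrl):
    """Equal-variance two-sample t-test from the pooled-SD formula."""
    case, ctrl = np.asarray(case, float), np.asarray(ctrl, float)
    n1, n2 = case.size, ctrl.size
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / (
        n1 + n2 - 2
    )
    t = (case.mean() - ctrl.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def normal_equation_loglog_fit(degree_map):
    """Closed-form least squares of log(count) on log(degree)."""
    vals = [d for d in degree_map.values() if d >= 1]
    uniq, counts = np.unique(np.asarray(vals), return_counts=True)
    x, y = np.log(uniq.astype(float)), np.log(counts.astype(float))
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    yhat = intercept + slope * x
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return math.exp(intercept), slope, 1 - ss_res / ss_tot


def manual_pearson(x, y):
    """Pearson r from the covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def random_connected_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Small random connected graph: a random spanning tree plus extras."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        g.add_edge(int(order[i]), int(order[rng.integers(i)]))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.integers(n, size=2)
        if a != b:
            g.add_edge(int(a), int(b))
    return g
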