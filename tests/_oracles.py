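"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles (explicit Floyd-Warshall,
exhaustive shortest-path counting, hand union-find, rank-then-Pearson
Spearman, sum-of-squares ANOVA) and deliberately shares no code with the
package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = float("inf")


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances with d_ij = 1 / w_ij."""
    n = W.shape[0]
    D = np.full((n, n), INF)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = D[i, k] + D[k, j]
                if alt < D[i, j]:
                    D[i, j] = alt
    return D


def lp(W: np.ndarray) -> float:
    """Mean shortest-path distance over connected ordered pairs."""
    D = floyd_warshall(W)
    vals = [
        D[i, j]
        for i in range(W.shape[0])
        for j in range(W.shape[0])
        if i != j and math.isfinite(D[i, j])
    ]
    return sum(vals) / len(vals) if vals else float("nan")


def eglob(W: np.ndarray) -> float:
    """Mean inverse distance over all ordered pairs (0 when disconnected)."""
    n = W.shape[0]
    D = floyd_warshall(W)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    D = floyd_warshall(W)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and math.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
        out[i] = acc / (n - 1)
    return out


def clustering(W: np.ndarray) -> float:
    """Onnela geometric-mean weighted clustering, max-normalized, averaged."""
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return 0.0
    Wn = W / wmax
    coeffs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        acc = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and W[j, h] > 0:
                    acc += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        coeffs.append(acc / (k * (k - 1)))
    return float(np.mean(coeffs))


def eloc(W: np.ndarray) -> float:
    """Mean global efficiency of each node's neighbor-induced subgraph."""
    n = W.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        vals.append(eglob(sub))
    return float(np.mean(vals))


def betweenness(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fraction-weighted shortest-path counts through each node.

    Path counts by dynamic programming over nodes ordered by distance from
    the source; each unordered source-target pair counts once.
    """
    n = W.shape[0]
    D = floyd_warshall(W)
    bc = np.zeros(n)

    def n_shortest_paths(s: int) -> np.ndarray:
        sigma = np.zeros(n)
        sigma[s] = 1.0
        order = sorted(range(n), key=lambda v: D[s, v])
        for v in order:
            if v == s or not math.isfinite(D[s, v]):
                continue
            for u in range(n):
                if W[u, v] > 0 and math.isfinite(D[s, u]):
                    if abs(D[s, u] + 1.0 / W[u, v] - D[s, v]) < tol:
                        sigma[v] += sigma[u]
        return sigma

    sig = np.array([n_shortest_paths(s) for s in range(n)])
    for s, t in itertools.combinations(range(n), 2):
        if not math.isfinite(D[s, t]) or sig[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if math.isfinite(D[s, v]) and math.isfinite(D[v, t]):
                if abs(D[s, v] + D[v, t] - D[s, t]) < tol:
                    bc[v] += sig[s, v] * sig[v, t] / sig[s, t]
    return bc


def union_find_components(
    edges: list[tuple[int, int]]
) -> list[set[tuple[int, int]]]:
    """Edge components (edges linked through shared nodes) via union-find."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[tuple[int, int]]] = {}
    for e in edges:
        comps.setdefault(find(e[0]), set()).add(e)
    return list(comps.values())


def spearman(x, y) -> float:
    """Average-rank Spearman rho: rank by hand, then Pearson on the ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def anova_f(groups: list[list[float]]) -> float:
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(
        len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups
    )
    ss_within = sum(
        (v - sum(g) / len(g)) ** 2 for g in groups for v in g
    )
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def two_sample_t(a: list[float], b: list[float]) -> float:
    """Pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, by hand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def random_weighted_graph(
    rng: np.random.Generator, n: int, density: float = 0.4
) -> np.ndarray:
    """A random symmetric weighted matrix for oracle-equivalence checks."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
    return W
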