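"""Independent brute-force oracles for the graph measures and statistics.

Everything here is written as directly as possible from the definitions
(triple loops, exhaustive enumeration, closed forms) and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


# ---------------------------------------------------------------------------
# Distances (Floyd-Warshall, triple loop)
# ---------------------------------------------------------------------------


def oracle_distance(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_cpl(d: np.ndarray) -> float:
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d))
            if i != j and math.isfinite(d[i, j])]
    return sum(vals) / len(vals)


def oracle_global_efficiency(d: np.ndarray) -> float:
    n = len(d)
    vals = [1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals)


def oracle_ecc_radius_diameter(d: np.ndarray):
    """(per-node ecc, mean, radius, diameter) on the largest component."""
    n = len(d)
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if math.isfinite(d[i, j])]
        seen.update(comp)
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    comp = comps[0]
    ecc = {i: max(d[i, j] for j in comp) for i in comp}
    values = list(ecc.values())
    return ecc, sum(values) / len(values), min(values), max(values)


# ---------------------------------------------------------------------------
# Triangle measures (direct summation over all triples)
# ---------------------------------------------------------------------------


def oracle_clustering(w: np.ndarray):
    """Per-node Onnela clustering and mean (w normalized by matrix max)."""
    n = w.shape[0]
    wmax = w.max()
    what = w / wmax if wmax > 0 else w
    per_node = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            per_node.append(0.0)
            continue
        s = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            s += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        per_node.append(2.0 * s / (k * (k - 1)))
    return np.array(per_node), float(np.mean(per_node))


def oracle_transitivity(w: np.ndarray) -> float:
    n = w.shape[0]
    wmax = w.max()
    what = w / wmax if wmax > 0 else w
    num = 0.0
    den = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        den += k * (k - 1)
        for j, h in itertools.combinations(nbrs, 2):
            num += 2.0 * (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
    return num / den


def oracle_local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += oracle_global_efficiency(oracle_distance(sub))
    return total / n


# ---------------------------------------------------------------------------
# Betweenness (explicit shortest-path counting per pair)
# ---------------------------------------------------------------------------


def oracle_betweenness(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Normalized betweenness by counting geodesics with a recursive walk
    over the (oracle) distance matrix."""
    n = w.shape[0]
    d = oracle_distance(w)
    score = np.zeros(n)

    def paths_through(s, t):
        """(number of s-t geodesics, count of geodesics through each v)."""
        sigma = np.zeros(n)
        through = np.zeros((n, n))  # through[v] accumulated later

        # count geodesics from u to t recursively
        memo: dict[int, tuple[float, np.ndarray]] = {}

        def walk(u):
            if u == t:
                inner = np.zeros(n)
                return 1.0, inner
            if u in memo:
                return memo[u]
            count = 0.0
            inner = np.zeros(n)
            for v in range(n):
                if v != u and w[u, v] > 0 and math.isfinite(d[v, t]):
                    if abs((1.0 / w[u, v]) + d[v, t] - d[u, t]) <= tol * max(
                        1.0, d[u, t]
                    ):
                        c, thr = walk(v)
                        count += c
                        inner += thr
                        if v != t:
                            inner[v] += c
            memo[u] = (count, inner)
            return memo[u]

        return walk(s)

    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s, t]):
                continue
            count, thr = paths_through(s, t)
            if count > 0:
                score += thr / count
    return score / ((n - 1) * (n - 2) / 2.0)


# ---------------------------------------------------------------------------
# Assortativity and modularity
# ---------------------------------------------------------------------------


def oracle_assortativity(w: np.ndarray):
    n = w.shape[0]
    strength = w.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] != 0:
                xs += [strength[i], strength[j]]
                ys += [strength[j], strength[i]]
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0:
        return None
    sx, sy = xs - xs.mean(), ys - ys.mean()
    return float((sx * sy).sum()
                 / math.sqrt((sx**2).sum() * (sy**2).sum()))


def set_partitions(items):
    """All partitions of a list (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def oracle_modularity_q(w: np.ndarray, partition) -> float:
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for community in partition:
        for i in community:
            for j in community:
                q += (w[i, j] - k[i] * k[j] / two_m) / two_m
    return q


def oracle_modularity_max(w: np.ndarray) -> float:
    n = w.shape[0]
    return max(oracle_modularity_q(w, p) for p in set_partitions(range(n)))


# ---------------------------------------------------------------------------
# Binary-graph formulas (independent of the weighted code path)
# ---------------------------------------------------------------------------


def oracle_binary_distance(a: np.ndarray) -> np.ndarray:
    """Hop counts via breadth-first search."""
    n = a.shape[0]
    d = np.full((n, n), INF)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if a[u, v] and d[s, v] == INF:
                        d[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return d


def oracle_binary_clustering(a: np.ndarray):
    """Triangles over connected triples per node."""
    n = a.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        tri = sum(a[j, h] for j, h in itertools.combinations(nbrs, 2))
        out.append(2.0 * tri / (k * (k - 1)))
    return np.array(out), float(np.mean(out))


def oracle_binary_transitivity(a: np.ndarray) -> float:
    n = a.shape[0]
    triangles = 0
    triads = 0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        triads += k * (k - 1)
        triangles += sum(
            a[j, h] for j, h in itertools.combinations(nbrs, 2))
    return 2.0 * triangles / triads


# ---------------------------------------------------------------------------
# Graph enumeration and random graphs
# ---------------------------------------------------------------------------


def _is_connected(a: np.ndarray) -> bool:
    n = a.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in range(n):
            if a[u, v] and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def all_connected_binary_graphs(n: int):
    """Every connected labeled simple graph on n nodes (adjacency)."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(1, 2 ** len(pairs)):
        a = np.zeros((n, n))
        for idx, (i, j) in enumerate(pairs):
            if bits >> idx & 1:
                a[i, j] = a[j, i] = 1.0
        if _is_connected(a):
            yield a


def random_weighted_graph(rng: np.random.Generator, n: int,
                          p: float = 0.6) -> np.ndarray:
    """Random connected weighted graph, weights in (0.2, 1.0)."""
    while True:
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
        if _is_connected(w > 0):
            return w


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


def oracle_partial_correlation(x, y, z1, z2) -> float:
    """Recursive partial-correlation formula r_xy.z1z2."""

    def r(a, b):
        a = np.asarray(a, float) - np.mean(a)
        b = np.asarray(b, float) - np.mean(b)
        return float((a * b).sum()
                     / math.sqrt((a**2).sum() * (b**2).sum()))

    def partial1(rab, rac, rbc):
        return (rab - rac * rbc) / math.sqrt((1 - rac**2) * (1 - rbc**2))

    r_xy_z1 = partial1(r(x, y), r(x, z1), r(y, z1))
    r_xz2_z1 = partial1(r(x, z2), r(x, z1), r(z2, z1))
    r_yz2_z1 = partial1(r(y, z2), r(y, z1), r(z2, z1))
    return partial1(r_xy_z1, r_xz2_z1, r_yz2_z1)


def oracle_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up, spelled out."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted
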