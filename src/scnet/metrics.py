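"""Weighted and binary graph measures for covariance networks.

Implements the 13 global measures reported for each group network (average
degree, average strength, radius, diameter, eccentricity, characteristic
path length, global efficiency, local efficiency, mean clustering
coefficient, transitivity, modularity, assortativity, small-worldness) and
nodal betweenness centrality.

Conventions (the BRAPH family of definitions):

* weighted shortest paths use edge length ``1 / weight``;
* weighted clustering is the Onnela geometric-mean triangle formula on
  weights normalized by the network maximum, which reduces exactly to the
  binary triangle formula on 0/1 matrices;
* betweenness is normalized by ``(N-1)(N-2)/2`` so values lie in [0, 1];
* disconnected graphs: path length and eccentricity are computed on
  reachable pairs / the largest component with a warning, efficiency uses
  ``1/inf = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .networks import BinaryNetwork, GroupNetwork

__all__ = [
    "MetricError",
    "DisconnectedGraphWarning",
    "MetricPanel",
    "GLOBAL_MEASURES",
    "MEASURE_DISPLAY_NAMES",
    "degree_strength",
    "distance_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "eccentricity_radius_diameter",
    "clustering_coefficient",
    "transitivity",
    "local_efficiency",
    "betweenness_centrality",
    "modularity",
    "assortativity",
    "small_worldness",
    "compute_metric_panel",
    "global_measure_values",
]


class MetricError(ValueError):
    """Raised when a measure is undefined for the given graph."""


class DisconnectedGraphWarning(UserWarning):
    """The graph is disconnected; the measure was restricted to reachable
    pairs / the largest component."""


#: The 13 global measures, in report (Table) order.
GLOBAL_MEASURES: tuple[str, ...] = (
    "average_degree",
    "average_strength",
    "radius",
    "diameter",
    "eccentricity",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering_coefficient",
    "transitivity",
    "modularity",
    "assortativity",
    "small_worldness",
)

MEASURE_DISPLAY_NAMES: dict[str, str] = {
    "average_degree": "Average degree",
    "average_strength": "Average strength",
    "radius": "Radius",
    "diameter": "Diameter",
    "eccentricity": "Eccentricity",
    "characteristic_path_length": "Characteristic path length",
    "global_efficiency": "Global efficiency",
    "local_efficiency": "Local efficiency",
    "mean_clustering_coefficient": "Mean clustering coefficient",
    "transitivity": "Transitivity",
    "modularity": "Modularity",
    "assortativity": "Assortativity",
    "small_worldness": "Small-worldness index",
}


def _as_weights(net: GroupNetwork | BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, GroupNetwork):
        return net.weights
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float)
    w = np.asarray(net, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MetricError("weight matrix must be square")
    return w


def _require_nonnegative(w: np.ndarray) -> None:
    if w.min() < 0:
        raise MetricError(
            "negative edge weights present; apply the zero_negative or "
            "absolute weight policy before computing path-based measures"
        )


# ---------------------------------------------------------------------------
# Degree / strength
# ---------------------------------------------------------------------------


def degree_strength(net) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-node degree (count of incident edges) and strength (sum of
    incident weights), plus their node averages."""
    w = _as_weights(net)
    degree = (w != 0).sum(axis=1).astype(float)
    strength = w.sum(axis=1)
    n = len(degree)
    if n == 0:
        return degree, strength, 0.0, 0.0
    return degree, strength, float(degree.mean()), float(strength.mean())


# ---------------------------------------------------------------------------
# Shortest paths and derived measures
# ---------------------------------------------------------------------------


def distance_matrix(net) -> np.ndarray:
    """All-pairs shortest-path lengths (Dijkstra).

    Weighted edges have length ``1/weight``; binary graphs reduce to hop
    counts.  Unreachable pairs are ``+inf``; the diagonal is 0.
    """
    w = _as_weights(net)
    _require_nonnegative(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def characteristic_path_length(dist: np.ndarray) -> float:
    """Mean shortest-path length over ordered pairs of distinct nodes.

    Unreachable pairs are excluded (with a :class:`DisconnectedGraphWarning`
    when any exist).
    """
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    values = dist[off]
    finite = np.isfinite(values)
    if not finite.any():
        raise MetricError("no finite off-diagonal distances")
    if not finite.all():
        warnings.warn(
            "graph is disconnected; characteristic path length computed "
            "over reachable pairs only",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    return float(values[finite].mean())


def global_efficiency(dist: np.ndarray) -> float:
    """Mean of inverse shortest-path lengths over ordered pairs
    (``1/inf = 0`` for unreachable pairs)."""
    n = dist.shape[0]
    if n < 2:
        raise MetricError("global efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].mean())


def _components_from_distances(dist: np.ndarray) -> list[np.ndarray]:
    n = dist.shape[0]
    unassigned = np.ones(n, dtype=bool)
    comps: list[np.ndarray] = []
    for i in range(n):
        if not unassigned[i]:
            continue
        members = np.flatnonzero(np.isfinite(dist[i]) & unassigned)
        unassigned[members] = False
        comps.append(members)
    return comps


@dataclass(frozen=True)
class EccentricityResult:
    per_node: np.ndarray  # NaN for nodes outside the analyzed component
    mean: float
    radius: float
    diameter: float
    component: np.ndarray  # node indices of the analyzed component


def eccentricity_radius_diameter(dist: np.ndarray) -> EccentricityResult:
    """Node eccentricities (max finite distance), radius (min eccentricity),
    diameter (max), and the node-mean eccentricity.

    On a disconnected graph, computed on the largest connected component
    (ties broken toward the component containing the smallest node index)
    with a warning; nodes outside it get NaN.
    """
    n = dist.shape[0]
    comps = _components_from_distances(dist)
    comps.sort(key=lambda c: (-len(c), int(c.min())))
    comp = comps[0]
    if len(comps) > 1:
        warnings.warn(
            "graph is disconnected; eccentricity/radius/diameter computed "
            "on the largest connected component",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    if len(comp) < 2:
        raise MetricError(
            "largest component is a singleton; eccentricity undefined"
        )
    sub = dist[np.ix_(comp, comp)]
    ecc = sub.max(axis=1)
    per_node = np.full(n, np.nan)
    per_node[comp] = ecc
    return EccentricityResult(
        per_node=per_node,
        mean=float(ecc.mean()),
        radius=float(ecc.min()),
        diameter=float(ecc.max()),
        component=comp,
    )


# ---------------------------------------------------------------------------
# Triangle-based measures
# ---------------------------------------------------------------------------


def _triangle_values(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node geometric-mean triangle intensity and degree.

    ``t_i = sum_{j,h} (w_ij w_jh w_hi)^{1/3}`` over ordered pairs (j, h),
    with weights normalized by the network maximum (Onnela).  On a 0/1
    matrix this is exactly twice the triangle count at each node.
    """
    _require_nonnegative(w)
    wmax = w.max()
    w_hat = w / wmax if wmax > 0 else w
    m = np.cbrt(w_hat)
    t = np.einsum("ij,jh,hi->i", m, m, m)
    degree = (w != 0).sum(axis=1).astype(float)
    return t, degree


def clustering_coefficient(net) -> tuple[np.ndarray, float]:
    """Per-node Onnela clustering coefficient and its node mean.

    ``C_i = t_i / (k_i (k_i - 1))``; nodes with degree < 2 have ``C_i = 0``.
    Reduces to triangles / connected triples on binary graphs.
    """
    w = _as_weights(net)
    t, k = _triangle_values(w)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean()) if len(c) else 0.0


def transitivity(net) -> float:
    """Weighted transitivity: total triangle intensity over total connected
    triples (``3 x triangles / triads`` on binary graphs)."""
    w = _as_weights(net)
    t, k = _triangle_values(w)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        raise MetricError("no connected triples; transitivity undefined")
    return float(t.sum() / denom)


def local_efficiency(net) -> float:
    """Node-mean of the global efficiency of each node's neighbor subgraph.

    Distances inside the subgraph use the original weights (1/w lengths);
    nodes with fewer than 2 neighbors contribute 0.
    """
    w = _as_weights(net)
    _require_nonnegative(w)
    n = w.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, 0.0)
        # Floyd-Warshall: faster than Dijkstra on these small dense subgraphs
        d = shortest_path(lengths, method="FW", directed=False)
        np.fill_diagonal(d, 0.0)
        total += global_efficiency(d)
    return total / n


# ---------------------------------------------------------------------------
# Betweenness centrality
# ---------------------------------------------------------------------------


def betweenness_centrality(net) -> np.ndarray:
    """Normalized betweenness: the fraction of all-pairs shortest paths
    through each node, divided by ``(N-1)(N-2)/2`` so values lie in [0, 1].

    Weighted graphs use ``1/weight`` edge lengths.
    """
    w = _as_weights(net)
    _require_nonnegative(w)
    n = w.shape[0]
    if n < 3:
        raise MetricError("betweenness needs at least 3 nodes")
    ii, jj = np.triu_indices(n, k=1)
    mask = w[ii, jj] > 0
    edges = np.column_stack([ii[mask], jj[mask]])
    if len(edges) == 0:
        return np.zeros(n)
    lengths = 1.0 / w[ii[mask], jj[mask]]
    g = ig.Graph(n=n, edges=edges.tolist())
    raw = np.asarray(g.betweenness(weights=lengths.tolist()), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2.0)


# ---------------------------------------------------------------------------
# Modularity and assortativity
# ---------------------------------------------------------------------------


def modularity(net, seed: int = 0,
               n_restarts: int = 8) -> tuple[list[set[int]], float]:
    """Louvain community detection maximizing weighted Newman modularity.

    Runs ``n_restarts`` seeded restarts (Louvain's greedy local moves can
    stall on small graphs) and returns the best partition (list of
    node-index sets) with its Q.  Deterministic for a fixed seed.
    """
    w = _as_weights(net)
    _require_nonnegative(w)
    if w.shape[0] == 0 or not (w > 0).any():
        raise MetricError("modularity undefined for an empty graph")
    g = nx.from_numpy_array(w)
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_q = -np.inf
    best: list[set[int]] = []
    for sub_seed in sub_seeds:
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=int(sub_seed % (2**31 - 1))
        )
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            best_q = q
            best = [set(c) for c in communities]
    return best, float(best_q)


def assortativity(net) -> float | None:
    """Strength assortativity: Pearson correlation of endpoint strengths
    over edges (each edge contributes both orientations).

    On binary graphs strength equals degree, giving the classical degree
    assortativity.  Returns ``None`` (an explicit undefined flag) when the
    endpoint strengths have zero variance, e.g. on a complete regular graph.
    """
    w = _as_weights(net)
    n = w.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    mask = w[ii, jj] != 0
    if not mask.any():
        raise MetricError("assortativity needs at least one edge")
    strength = w.sum(axis=1)
    a = np.concatenate([strength[ii[mask]], strength[jj[mask]]])
    b = np.concatenate([strength[jj[mask]], strength[ii[mask]]])
    if a.std() == 0 or b.std() == 0:
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Small-worldness
# ---------------------------------------------------------------------------


def _null_surrogate_edges(
    n: int, edges: np.ndarray, complete: bool, seed: int
) -> np.ndarray:
    """Degree-preserving rewired edge list (double-edge swaps, 10x|E|
    attempted swaps, simple-graph preserving).  A complete graph has no
    alternative topology and is returned unchanged."""
    import random

    n_edges = len(edges)
    if complete or n_edges < 2:
        return edges
    g = ig.Graph(n=n, edges=edges.tolist())
    state = random.getstate()
    try:
        # python-igraph draws from the stdlib random module by default,
        # which makes the C rewiring loop deterministic under random.seed
        random.seed(seed)
        g.rewire(n=10 * n_edges)
    finally:
        random.setstate(state)
    out = np.asarray(g.get_edgelist(), dtype=int)
    if len(out) != n_edges or not np.array_equal(
        np.bincount(out.ravel(), minlength=n),
        np.bincount(edges.ravel(), minlength=n),
    ):
        raise MetricError(
            f"degree-preserving rewiring failed (n={n}, E={n_edges})"
        )
    return out


def small_worldness(net, n_null: int = 100, seed: int = 0) -> float:
    """Small-worldness index sigma = (C / C_null) / (L / L_null).

    C is the mean (Onnela) clustering coefficient and L the characteristic
    path length; null values are means over ``n_null`` degree-preserving
    rewired surrogates (double-edge swaps, 10x|E| swaps).  For weighted
    graphs the observed weight multiset is shuffled onto the rewired
    topology.  On a complete graph no alternative topology exists, so the
    surrogate keeps the observed edges (and sigma is exactly 1 for binary
    complete graphs).  Deterministic for a fixed seed.
    """
    w = _as_weights(net)
    _require_nonnegative(w)
    if n_null < 20:
        raise MetricError("n_null must be at least 20")
    n = w.shape[0]
    dist = distance_matrix(w)
    if not np.isfinite(dist).all():
        raise MetricError("small-worldness requires a connected graph")
    _, c_obs = clustering_coefficient(w)
    l_obs = characteristic_path_length(dist)

    ii, jj = np.triu_indices(n, k=1)
    mask = w[ii, jj] > 0
    edge_weights = w[ii[mask], jj[mask]]
    n_edges = int(mask.sum())
    complete = n_edges == n * (n - 1) // 2
    base_edges = np.column_stack([ii[mask], jj[mask]])

    seeds = np.random.SeedSequence(seed).generate_state(2 * n_null)
    rng = np.random.default_rng(seeds[0])
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for s in range(n_null):
        swap_seed = int(seeds[n_null + s] % (2**31 - 1))
        edges = _null_surrogate_edges(n, base_edges, complete, swap_seed)
        shuffled = rng.permutation(edge_weights)
        w_null = np.zeros_like(w)
        w_null[edges[:, 0], edges[:, 1]] = shuffled
        w_null[edges[:, 1], edges[:, 0]] = shuffled
        _, c_null[s] = clustering_coefficient(w_null)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DisconnectedGraphWarning)
            l_null[s] = characteristic_path_length(distance_matrix(w_null))
    c_bar = float(c_null.mean())
    l_bar = float(l_null.mean())
    if c_bar == 0 or l_obs == 0:
        raise MetricError(
            "small-worldness undefined: null clustering or observed path "
            "length is zero"
        )
    return float((c_obs / c_bar) / (l_obs / l_bar))


def _small_worldness_lcc(w: np.ndarray, n_null: int, seed: int) -> float:
    """Small-worldness, falling back to the largest connected component
    when the graph is disconnected (with a warning)."""
    dist = distance_matrix(w)
    if np.isfinite(dist).all():
        return small_worldness(w, n_null=n_null, seed=seed)
    comps = _components_from_distances(dist)
    comps.sort(key=lambda c: (-len(c), int(c.min())))
    comp = comps[0]
    if len(comp) < 3:
        raise MetricError(
            "largest component too small for small-worldness"
        )
    warnings.warn(
        "graph is disconnected; small-worldness computed on the largest "
        "connected component",
        DisconnectedGraphWarning,
        stacklevel=2,
    )
    return small_worldness(w[np.ix_(comp, comp)], n_null=n_null, seed=seed)


# ---------------------------------------------------------------------------
# Metric panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricPanel:
    """The 13 global measures plus nodal betweenness for one network."""

    group: str
    average_degree: float
    average_strength: float
    radius: float
    diameter: float
    eccentricity: float
    characteristic_path_length: float
    global_efficiency: float
    local_efficiency: float
    mean_clustering_coefficient: float
    transitivity: float
    modularity: float
    assortativity: float | None
    assortativity_defined: bool
    small_worldness: float
    betweenness: np.ndarray
    connected: bool
    seed: int
    config_hash: str

    def global_values(self) -> dict[str, float | None]:
        """The 13 global measures in report order."""
        return {name: getattr(self, name) for name in GLOBAL_MEASURES}


def global_measure_values(
    weights: np.ndarray,
    measures: tuple[str, ...] = GLOBAL_MEASURES,
    seed: int = 0,
    n_null: int = 20,
) -> np.ndarray:
    """Vector of global measure values on a weight matrix.

    Shares one distance matrix across the path-based measures; an
    undefined assortativity maps to NaN here (the panel keeps the explicit
    flag).  This is the fast path used inside permutation loops.
    """
    w = np.asarray(weights, dtype=float)
    unknown = [m for m in measures if m not in GLOBAL_MEASURES]
    if unknown:
        raise MetricError(f"unknown measures: {unknown}")
    dist: np.ndarray | None = None

    def _dist() -> np.ndarray:
        nonlocal dist
        if dist is None:
            dist = distance_matrix(w)
        return dist

    out = np.empty(len(measures))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        for idx, name in enumerate(measures):
            if name == "average_degree":
                out[idx] = degree_strength(w)[2]
            elif name == "average_strength":
                out[idx] = degree_strength(w)[3]
            elif name == "radius":
                out[idx] = eccentricity_radius_diameter(_dist()).radius
            elif name == "diameter":
                out[idx] = eccentricity_radius_diameter(_dist()).diameter
            elif name == "eccentricity":
                out[idx] = eccentricity_radius_diameter(_dist()).mean
            elif name == "characteristic_path_length":
                out[idx] = characteristic_path_length(_dist())
            elif name == "global_efficiency":
                out[idx] = global_efficiency(_dist())
            elif name == "local_efficiency":
                out[idx] = local_efficiency(w)
            elif name == "mean_clustering_coefficient":
                out[idx] = clustering_coefficient(w)[1]
            elif name == "transitivity":
                out[idx] = transitivity(w)
            elif name == "modularity":
                out[idx] = modularity(w, seed=seed)[1]
            elif name == "assortativity":
                r = assortativity(w)
                out[idx] = np.nan if r is None else r
            elif name == "small_worldness":
                out[idx] = _small_worldness_lcc(w, n_null=n_null, seed=seed)
    return out


def compute_metric_panel(
    net: GroupNetwork | BinaryNetwork | np.ndarray,
    config: dict | None = None,
    seed: int = 0,
) -> MetricPanel:
    """Assemble the full 13-measure panel plus nodal betweenness.

    ``config`` may set ``n_null_graphs`` (small-world surrogates, default
    100).  The seed fixes modularity optimization and the small-world null;
    identical inputs and seed give identical panels.
    """
    from .pipeline import config_digest  # local import to avoid a cycle

    config = dict(config or {})
    n_null = int(config.get("n_null_graphs", 100))
    w = _as_weights(net)
    group = getattr(net, "group", "")
    dist = distance_matrix(w)
    connected = bool(np.isfinite(dist).all())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        deg, stren, avg_deg, avg_stren = degree_strength(w)
        ecc = eccentricity_radius_diameter(dist)
        cpl = characteristic_path_length(dist)
        geff = global_efficiency(dist)
        leff = local_efficiency(w)
        _, clus = clustering_coefficient(w)
        trans = transitivity(w)
        _, q = modularity(w, seed=seed)
        assort = assortativity(w)
        sw = _small_worldness_lcc(w, n_null=n_null, seed=seed)
        betw = betweenness_centrality(w)
    if not connected:
        warnings.warn(
            f"group {group!r}: network is disconnected; path-based "
            "measures restricted to reachable pairs / largest component",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    return MetricPanel(
        group=group,
        average_degree=avg_deg,
        average_strength=avg_stren,
        radius=ecc.radius,
        diameter=ecc.diameter,
        eccentricity=ecc.mean,
        characteristic_path_length=cpl,
        global_efficiency=geff,
        local_efficiency=leff,
        mean_clustering_coefficient=clus,
        transitivity=trans,
        modularity=q,
        assortativity=assort,
        assortativity_defined=assort is not None,
        small_worldness=sw,
        betweenness=betw,
        connected=connected,
        seed=int(seed),
        config_hash=config_digest({"n_null_graphs": n_null}),
    )
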