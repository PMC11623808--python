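"""Population graphs: network families, validation and amplification.

A population graph is a simple, undirected, connected graph whose nodes are
individuals and whose edges are the routes along which offspring replace
neighbours.  The generators cover the families used to span amplifier /
suppressor space: complete, star, modified star, k-regular, Erdos-Renyi,
small world, complete bipartite, two-cluster random geometric,
degree-exponent preferential attachment, PA stars (i fully connected core
nodes plus leaves attached to every core node), detour graphs (a clique
with one edge replaced by a path) and random trees, including ductal-like
branching trees standing in for imaged ductal networks.

The Birth-death amplification factor of a graph is estimated empirically:
run the constant-selection process (no niche separation) with a small probe
advantage, then invert the classical fixation closed form
``Phi = (1 - (1+s)^-a) / (1 - (1+s)^-aN)`` for a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PopulationGraph",
    "GraphFamilySpec",
    "AmplificationEstimate",
    "GraphConstructionError",
    "generate",
    "complete_graph",
    "star_graph",
    "modified_star_graph",
    "k_regular_graph",
    "erdos_renyi_graph",
    "small_world_graph",
    "bipartite_graph",
    "random_geometric_graph",
    "preferential_attachment_graph",
    "pa_star_graph",
    "detour_graph",
    "random_tree",
    "random_ductal_tree",
    "degree_preserving_randomize",
    "estimate_amplification",
]


class GraphConstructionError(ValueError):
    """Parameters cannot yield a valid (simple, connected) graph."""


class PopulationGraph:
    """Validated wrapper around an undirected simple connected graph.

    Nodes are relabelled to contiguous 0-based integers (sorted order of the
    original labels); the mapping is kept in ``node_mapping``.
    """

    def __init__(self, graph: nx.Graph):
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("population graphs are undirected and simple")
        if graph.number_of_nodes() < 2:
            raise ValueError("population graphs need at least 2 nodes")
        if any(u == v for u, v in graph.edges()):
            raise ValueError("self-loops are not allowed")
        if not nx.is_connected(graph):
            raise ValueError("population graphs must be connected")
        nodes = sorted(graph.nodes(), key=lambda v: (str(type(v)), v))
        self.node_mapping = {v: k for k, v in enumerate(nodes)}
        self.nx_graph = nx.relabel_nodes(graph, self.node_mapping, copy=True)

    @property
    def n_nodes(self) -> int:
        return self.nx_graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.nx_graph.number_of_edges()

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.nx_graph.edges())

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.nx_graph.degree(v) for v in range(self.n_nodes)])

    def laplacian(self):
        """Combinatorial Laplacian L = D - A (scipy sparse)."""
        return nx.laplacian_matrix(self.nx_graph, nodelist=range(self.n_nodes))

    def is_regular(self) -> bool:
        d = self.degrees
        return bool((d == d[0]).all())

    def __eq__(self, other):
        return (
            isinstance(other, PopulationGraph)
            and self.n_nodes == other.n_nodes
            and self.edges == other.edges
        )

    def __repr__(self):
        return f"PopulationGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# generators


def complete_graph(n: int) -> PopulationGraph:
    return PopulationGraph(nx.complete_graph(n))


def star_graph(n: int) -> PopulationGraph:
    """Hub (node 0) connected to n - 1 leaves."""
    return PopulationGraph(nx.star_graph(n - 1))


def modified_star_graph(n: int, m: int, seed=None) -> PopulationGraph:
    """Star with m extra random edges between distinct non-adjacent pairs."""
    rng = np.random.default_rng(seed)
    g = nx.star_graph(n - 1)
    missing = [(u, v) for u in range(1, n) for v in range(u + 1, n)]
    if m > len(missing):
        raise GraphConstructionError("more extra edges requested than available pairs")
    idx = rng.choice(len(missing), size=m, replace=False)
    g.add_edges_from(missing[k] for k in idx)
    return PopulationGraph(g)


def k_regular_graph(n: int, k: int, seed=None) -> PopulationGraph:
    if (n * k) % 2 != 0 or k >= n:
        raise GraphConstructionError("k-regular graph needs n*k even and k < n")
    return _retry_connected(
        lambda s: nx.random_regular_graph(k, n, seed=s), seed, "k-regular"
    )


def erdos_renyi_graph(n: int, p: float, seed=None) -> PopulationGraph:
    return _retry_connected(
        lambda s: nx.erdos_renyi_graph(n, p, seed=s), seed, "Erdos-Renyi"
    )


def small_world_graph(n: int, k: int, p: float, seed=None) -> PopulationGraph:
    return _retry_connected(
        lambda s: nx.watts_strogatz_graph(n, k, p, seed=s), seed, "small-world"
    )


def bipartite_graph(n1: int, n2: int) -> PopulationGraph:
    return PopulationGraph(nx.complete_bipartite_graph(n1, n2))


def random_geometric_graph(
    n: int = 100,
    seed=None,
    *,
    cluster_means: tuple[float, float] = (0.0, 3.0),
    variance: float = 0.25,
    radius_step: float = 0.05,
) -> PopulationGraph:
    """Two-cluster planar geometric graph.

    Half the x coordinates are drawn around each cluster mean and all y
    coordinates around 0, with the given variance; nodes within the cut-off
    radius are joined.  The radius starts at the smallest value giving a
    connected graph (found by sweeping upward from the largest nearest-
    neighbour gap) — pass ``radius_factor`` in ``generate`` to scale it up
    towards the complete graph.
    """
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(variance))
    half = n // 2
    x = np.concatenate(
        [rng.normal(cluster_means[0], sd, half), rng.normal(cluster_means[1], sd, n - half)]
    )
    y = rng.normal(0.0, sd, n)
    pts = np.c_[x, y]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    # smallest connecting radius: bisect over the sorted pairwise distances
    dist_sorted = np.unique(d[np.triu_indices(n, 1)])

    def connected(r):
        return nx.is_connected(nx.from_numpy_array((d <= r) & ~np.eye(n, dtype=bool)))

    lo, hi = 0, len(dist_sorted) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(dist_sorted[mid]):
            hi = mid
        else:
            lo = mid + 1
    r = dist_sorted[lo]
    g = nx.from_numpy_array((d <= r) & ~np.eye(n, dtype=bool))
    return PopulationGraph(g)


def preferential_attachment_graph(
    n: int, m: int = 3, beta: float = 1.0, seed=None
) -> PopulationGraph:
    """Sequential attachment with probability proportional to degree**beta.

    Starts from a clique on m nodes; each new node attaches to m distinct
    existing nodes sampled without replacement with weight degree**beta.
    ``beta = 1`` is classical preferential attachment; large beta
    concentrates attachment on hubs, negative beta on low-degree nodes.
    """
    if m < 1 or m >= n:
        raise GraphConstructionError("need 1 <= m < n")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(m) if m > 1 else nx.empty_graph(1)
    for v in range(max(m, 1), n):
        existing = np.arange(v)
        deg = np.array([max(g.degree(u), 1) for u in existing], dtype=float)
        w = deg**beta
        w /= w.sum()
        targets = rng.choice(existing, size=min(m, v), replace=False, p=w)
        g.add_edges_from((v, int(t)) for t in targets)
    return PopulationGraph(g)


def pa_star_graph(n: int, i: int) -> PopulationGraph:
    """i fully connected core nodes; n - i leaves joined to every core node.

    i = 1 recovers the star, i = n - 1 the complete graph; equivalent to a
    preferential-attachment network with m = i in the infinite-exponent
    limit (every newcomer attaches to the i highest-degree nodes).
    """
    if not 1 <= i <= n - 1:
        raise GraphConstructionError("core size i must lie in [1, n-1]")
    g = nx.complete_graph(i)
    for leaf in range(i, n):
        g.add_edges_from((leaf, c) for c in range(i))
    return PopulationGraph(g)


def detour_graph(n1: int, n2: int, seed=None) -> PopulationGraph:
    """Clique on n1 nodes with one edge replaced by a path of n2 new nodes.

    The replaced edge is chosen uniformly; its endpoints become the ends of
    the detour path, so the graph has n1 + n2 nodes and
    ``C(n1, 2) - 1 + (n2 + 1)`` edges.
    """
    if n1 < 3:
        raise GraphConstructionError("detour graphs need a clique of at least 3")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(n1)
    edges = sorted(g.edges())
    u, v = edges[rng.integers(len(edges))]
    g.remove_edge(u, v)
    if n2 == 0:
        g.add_edge(u, v)
    else:
        path = list(range(n1, n1 + n2))
        g.add_edge(u, path[0])
        g.add_edges_from(zip(path[:-1], path[1:]))
        g.add_edge(path[-1], v)
    return PopulationGraph(g)


def random_tree(n: int, seed=None) -> PopulationGraph:
    return PopulationGraph(nx.random_labeled_tree(n, seed=_int_seed(seed)))


def random_ductal_tree(
    n: int, branching: float = 0.3, seed=None
) -> PopulationGraph:
    """Random tree with tunable branching, emulating duct-like architectures.

    Grows node by node: with probability ``branching`` the newcomer attaches
    to a uniformly chosen existing node (creating side branches), otherwise
    it extends the most recently added node (elongating a duct).
    ``branching = 0`` yields a path graph; values near 0.2-0.4 produce the
    long corridors punctuated by branch points seen in ductal trees.
    """
    if n < 2:
        raise GraphConstructionError("trees need at least 2 nodes")
    if not 0.0 <= branching <= 1.0:
        raise GraphConstructionError("branching must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_edge(0, 1)
    tip = 1
    for v in range(2, n):
        if rng.random() < branching:
            parent = int(rng.integers(v))
        else:
            parent = tip
        g.add_edge(v, parent)
        tip = v
    return PopulationGraph(g)


def _int_seed(seed) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(2**31 - 1))


def _retry_connected(builder, seed, name, retries: int = 200) -> PopulationGraph:
    rng = np.random.default_rng(seed)
    for _ in range(retries):
        g = builder(int(rng.integers(2**31 - 1)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            return PopulationGraph(g)
    raise GraphConstructionError(f"could not sample a connected {name} graph")


_FAMILIES = {
    "complete": lambda p, seed: complete_graph(p["n"]),
    "star": lambda p, seed: star_graph(p["n"]),
    "modified_star": lambda p, seed: modified_star_graph(p["n"], p["m"], seed),
    "k_regular": lambda p, seed: k_regular_graph(p["n"], p["k"], seed),
    "erdos_renyi": lambda p, seed: erdos_renyi_graph(p["n"], p["p"], seed),
    "small_world": lambda p, seed: small_world_graph(p["n"], p["k"], p["p"], seed),
    "bipartite": lambda p, seed: bipartite_graph(p["n1"], p["n2"]),
    "random_geometric": lambda p, seed: random_geometric_graph(
        p.get("n", 100), seed, variance=p.get("variance", 0.25)
    ),
    "preferential_attachment": lambda p, seed: preferential_attachment_graph(
        p["n"], p.get("m", 3), p.get("beta", 1.0), seed
    ),
    "pa_star": lambda p, seed: pa_star_graph(p["n"], p["i"]),
    "detour": lambda p, seed: detour_graph(p["n1"], p["n2"], seed),
    "random_tree": lambda p, seed: random_tree(p["n"], seed),
    "ductal_tree": lambda p, seed: random_ductal_tree(
        p["n"], p.get("branching", 0.3), seed
    ),
}


@dataclass(frozen=True)
class GraphFamilySpec:
    """A named family plus its parameters and RNG seed."""

    family: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise GraphConstructionError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )


def generate(spec: GraphFamilySpec) -> PopulationGraph:
    """Build the graph a :class:`GraphFamilySpec` describes (deterministic in seed)."""
    return _FAMILIES[spec.family](dict(spec.parameters), spec.seed)


# ---------------------------------------------------------------------------
# degree-preserving randomization


def degree_preserving_randomize(
    graph: PopulationGraph, n_swaps: int, seed=None
) -> PopulationGraph:
    """Double-edge swaps preserving the degree sequence and connectivity.

    Each attempt picks two independent edges (a, b), (c, d) and rewires to
    (a, d), (c, b); swaps creating self-loops, multi-edges or disconnection
    are rejected and skipped.
    """
    rng = np.random.default_rng(seed)
    g = graph.nx_graph.copy()
    if n_swaps == 0:
        return PopulationGraph(g)
    edges = list(g.edges())
    for _ in range(n_swaps):
        (a, b) = edges[rng.integers(len(edges))]
        (c, d) = edges[rng.integers(len(edges))]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        if nx.is_connected(g):
            edges = list(g.edges())
        else:  # undo
            g.remove_edge(a, d)
            g.remove_edge(c, b)
            g.add_edge(a, b)
            g.add_edge(c, d)
    return PopulationGraph(g)


# ---------------------------------------------------------------------------
# amplification factor


@dataclass(frozen=True)
class AmplificationEstimate:
    a_bd: float
    method: Literal["empirical_eq20", "weak_linear"]
    phi: float
    se: float
    s_probe: float
    replicates: int

    def __post_init__(self):
        if self.a_bd <= 0:
            raise ValueError("amplification factor must be positive")


def amplification_from_phi(
    phi: float, s_probe: float, N: int, a_max: float = 20.0
) -> float:
    """Invert ``Phi = (1 - (1+s)^-a)/(1 - (1+s)^-aN)`` for the factor a."""
    if not 0.0 < phi < 1.0:
        raise ValueError("fixation probability estimate must lie strictly in (0, 1)")
    logr = np.log1p(s_probe)

    def g(a):
        return np.expm1(-a * logr) / np.expm1(-a * N * logr) - phi

    lo, hi = 1e-3, a_max
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        hi = a_max * 10
        ghi = g(hi)
        if glo * ghi > 0:
            raise ValueError("no amplification factor in bracket; Phi inconsistent")
    return float(brentq(g, lo, hi, xtol=1e-10))


def estimate_amplification(
    graph: PopulationGraph,
    *,
    s_probe: float = 0.005,
    replicates: int = 100_000,
    seed: int = 0,
    method: Literal["empirical_eq20", "weak_linear"] = "empirical_eq20",
) -> AmplificationEstimate:
    """Estimate the Bd amplification factor from constant-selection runs.

    Runs the Moran Bd process with a beneficial probe mutant and no niche
    separation (identical generalists), estimates the fixation probability
    Phi, and converts it to a factor: ``empirical_eq20`` root-solves the
    classical closed form for a; ``weak_linear`` uses the weak-selection
    linearisation ``a = 2 (Phi - 1/N) / s``.
    """
    if s_probe <= 0:
        raise ValueError("s_probe must be positive")
    from .ecology import EcoEvoParams
    from .engine import SimulationConfig, estimate_fixation

    N = graph.n_nodes
    params = EcoEvoParams(N=N, s=s_probe, alpha=0.5)
    config = SimulationConfig(replicates=replicates, seed=seed)
    est = estimate_fixation(graph, params, config)
    phi, se = est.p_fix, est.se_fix
    if method == "weak_linear":
        a = 2.0 * (phi - 1.0 / N) / s_probe
        if a <= 0:
            raise ValueError("weak-linear estimate non-positive; increase replicates")
    else:
        a = amplification_from_phi(phi, s_probe, N)
    return AmplificationEstimate(a, method, phi, se, s_probe, replicates)
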