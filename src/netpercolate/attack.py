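"""Virtual-lesion simulations on thresholded connectomes.

A weighted connectome is binarized at each density of a proportional
threshold grid (keep the top fraction of edges by weight), then attacked
by removing nodes at random or in descending order of a centrality
computed once on the intact thresholded graph.  After each removal the
sizes of the two largest connected components are recorded; the
percolation point of a run is the fraction of nodes removed at which the
second-largest component first peaks - a disintegration criterion that
remains well defined on finite graphs, where the largest component only
vanishes when everything has been removed.  Attacks are iterated (ties in
the centrality ranking are permuted uniformly at random; random attacks
redraw the whole order) and the per-density mean percolation point forms
the functional response of the statistical stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._fast import batch_attack
from .types import (
    ComponentTrace,
    ConfigurationError,
    Connectome,
    DensityTooLowError,
    PercolationFunction,
    RemovalFrequencyMap,
)

__all__ = [
    "AttackConfig",
    "AttackResult",
    "proportional_threshold",
    "rank_nodes",
    "component_trace",
    "percolation_point",
    "run_attacks",
    "removal_frequency_map",
    "AttackSimulator",
    "default_density_grid",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "eigenvector", "betweenness")


def default_density_grid() -> np.ndarray:
    """Production grid: 0.25% to 100% in 0.25% steps (400 densities)."""
    return np.arange(1, 401) / 400.0


@dataclass
class AttackConfig:
    strategy: str = "random"
    densities: np.ndarray = field(default_factory=default_density_grid)
    n_iter: int = 100
    seed: int = 0
    recompute_centrality: bool = False  # re-rank after each removal (off: static ranking)

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"strategy must be one of {STRATEGIES}")
        d = np.asarray(self.densities, dtype=float)
        if d.ndim != 1 or len(d) == 0:
            raise ConfigurationError("densities must be a nonempty 1-d grid")
        if np.any(d <= 0) or np.any(d > 1):
            raise ConfigurationError("densities must lie in (0, 1]")
        if np.any(np.diff(d) <= 0):
            raise ConfigurationError("densities must be strictly increasing")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")


def _edge_count(density: float, n_nodes: int) -> int:
    # round half away from zero so densities map to identical edge counts
    # across implementations
    return int(math.floor(density * n_nodes * (n_nodes - 1) / 2 + 0.5))


def proportional_threshold(w: Connectome | np.ndarray, density: float) -> nx.Graph:
    """Keep the ``round(density * N(N-1)/2)`` largest-weight edges, binarized.

    Ties in weight are broken by lexicographic node-pair order.  The result
    is an unweighted graph on all N nodes (isolates allowed).
    """
    W = w.W if isinstance(w, Connectome) else np.asarray(w, dtype=float)
    if not 0 < density <= 1:
        raise ConfigurationError("density must be in (0, 1]")
    n = W.shape[0]
    m = _edge_count(density, n)
    if m == 0:
        raise DensityTooLowError("density too low for graph size")
    iu, ju = np.triu_indices(n, k=1)
    weights = W[iu, ju]
    # primary key: weight descending; ties: lexicographic (i, j) ascending
    order = np.lexsort((ju, iu, -weights))[:m]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[order].tolist(), ju[order].tolist()))
    return g


def _eigenvector_centrality(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Leading-eigenvector scores by power iteration, absolute values.

    On disconnected graphs the iteration converges to the dominant
    component's eigenvector; nodes outside it receive ~0 and fall to the
    end of the ranking (ties there are randomized by the caller).  The
    iteration runs on A + I, which has the same eigenvectors but a unique
    dominant eigenvalue even on bipartite graphs (where +/-lambda_max
    pairs would otherwise make plain power iteration oscillate).
    """
    n = adj.shape[0]
    if not adj.any():
        return np.zeros(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nv = adj @ v + v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros(n)
        nv /= norm
        if np.abs(nv - v).max() < tol:
            v = nv
            break
        v = nv
    return np.abs(v)


def _centrality(g: nx.Graph, strategy: str) -> np.ndarray:
    nodes = list(g.nodes)
    if strategy == "betweenness":
        bc = nx.betweenness_centrality(g, normalized=False)
        return np.array([bc[v] for v in nodes])
    if strategy == "eigenvector":
        adj = nx.to_numpy_array(g, nodelist=nodes)
        return _eigenvector_centrality(adj)
    raise ConfigurationError(f"no centrality for strategy {strategy!r}")


def _tie_randomized_order(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Descending order of ``values`` with ties permuted uniformly at random."""
    n = len(values)
    perm = rng.permutation(n)
    idx = np.argsort(-values[perm], kind="stable")
    return perm[idx]


def rank_nodes(g: nx.Graph, strategy: str, rng: np.random.Generator) -> list:
    """Removal order: uniform random permutation, or centrality-descending.

    Centralities are computed once on the intact graph; nodes sharing a
    centrality value are ordered uniformly at random.
    """
    if g.number_of_nodes() < 1:
        raise ConfigurationError("graph must have at least one node")
    nodes = list(g.nodes)
    if strategy == "random":
        return [nodes[i] for i in rng.permutation(len(nodes))]
    values = _centrality(g, strategy)
    return [nodes[i] for i in _tie_randomized_order(values, rng)]


def _graph_csr(g: nx.Graph) -> tuple[np.ndarray, np.ndarray, list]:
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for u, v in g.edges:
        neigh[index[u]].append(index[v])
        neigh[index[v]].append(index[u])
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + len(neigh[i])
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i in range(n):
        indices[indptr[i] : indptr[i + 1]] = neigh[i]
    return indptr, indices, nodes


def component_trace(g: nx.Graph, order: list) -> ComponentTrace:
    """Sizes of the two largest components after each removal in ``order``.

    Reference implementation via reverse union-find; ``order`` must be a
    permutation of the graph's nodes.  ``s2`` is 0 whenever fewer than two
    components remain.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if set(order) != set(nodes) or len(order) != n:
        raise ConfigurationError("order must be a permutation of the graph's nodes")
    indptr, indices, _ = _graph_csr(g)
    index = {v: i for i, v in enumerate(nodes)}
    pos = np.array([index[v] for v in order], dtype=np.int64)

    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    s1 = np.zeros(n, dtype=np.int64)
    s2 = np.zeros(n, dtype=np.int64)
    for k in range(n - 1, 0, -1):
        v = pos[k]
        parent[v] = v
        size[v] = 1
        for e in range(indptr[v], indptr[v + 1]):
            u = indices[e]
            if parent[u] != -1:
                ru, rv = find(u), find(v)
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
        roots = [x for x in range(n) if parent[x] == x]
        comp_sizes = sorted((int(size[x]) for x in roots), reverse=True)
        s1[k - 1] = comp_sizes[0] if comp_sizes else 0
        s2[k - 1] = comp_sizes[1] if len(comp_sizes) > 1 else 0
    # indexing: s1[k-1], s2[k-1] hold the state after removing the first k
    # nodes; the k = n entry (empty graph) is 0 by construction
    return ComponentTrace(s1=s1, s2=s2)


def percolation_point(trace: ComponentTrace) -> float:
    """Fraction of nodes removed at the first peak of the second component."""
    n = trace.n_steps
    if n < 1:
        raise ConfigurationError("trace must have at least one step")
    kstar = int(np.argmax(trace.s2)) + 1  # first index achieving the max
    return kstar / n


@dataclass
class AttackResult:
    """Per-subject attack outcome across the density grid.

    ``prefail_majority[d, v]`` is True when node ``v`` was removed strictly
    before the percolation step in at least half of the iterations at
    density ``d``.
    """

    subject_id: str
    strategy: str
    densities: np.ndarray
    mean_percolation: np.ndarray  # NaN where the density retained no edges
    prefail_majority: np.ndarray  # (densities, nodes) bool
    n_iter: int

    @property
    def percolation_function(self) -> PercolationFunction:
        return PercolationFunction(
            subject_id=self.subject_id,
            densities=self.densities.copy(),
            p=self.mean_percolation.copy(),
        )


def run_attacks(w: Connectome | np.ndarray, cfg: AttackConfig) -> AttackResult:
    """Threshold at each density and run ``n_iter`` attack iterations.

    The graph is thresholded once per density; targeted strategies compute
    the centrality once on the intact thresholded graph and re-randomize
    only ties across iterations, while random attacks redraw the whole
    order.  Deterministic given ``cfg.seed``.  Densities retaining no edge
    are recorded as NaN.
    """
    cfg.validate()
    W = w.W if isinstance(w, Connectome) else np.asarray(w, dtype=float)
    subject_id = w.subject_id if isinstance(w, Connectome) else ""
    n = W.shape[0]
    rng = np.random.default_rng(cfg.seed)
    densities = np.asarray(cfg.densities, dtype=float)
    mean_p = np.full(len(densities), np.nan)
    majority = np.zeros((len(densities), n), dtype=bool)

    for di, density in enumerate(densities):
        try:
            g = proportional_threshold(W, density)
        except DensityTooLowError:
            logger.warning(
                "subject %s: density %.4f retains no edges; recorded as missing",
                subject_id, density,
            )
            continue
        indptr, indices, _ = _graph_csr(g)
        if cfg.strategy == "random":
            orders = np.stack([rng.permutation(n) for _ in range(cfg.n_iter)])
        else:
            values = _centrality(g, cfg.strategy)
            if len(np.unique(values)) == n:  # no ties: iterations are identical
                one = _tie_randomized_order(values, rng)
                orders = np.tile(one, (cfg.n_iter, 1))
            else:
                orders = np.stack(
                    [_tie_randomized_order(values, rng) for _ in range(cfg.n_iter)]
                )
        perc, prefail_counts = batch_attack(indptr, indices, orders.astype(np.int64))
        mean_p[di] = perc.mean()
        majority[di] = prefail_counts * 2 >= cfg.n_iter
    return AttackResult(
        subject_id=subject_id,
        strategy=cfg.strategy,
        densities=densities,
        mean_percolation=mean_p,
        prefail_majority=majority,
        n_iter=cfg.n_iter,
    )


def removal_frequency_map(
    results: list[AttackResult],
    density: float,
    subject_ids: list[str] | None = None,
) -> RemovalFrequencyMap:
    """Fraction of subjects whose majority pre-failure set contains each node.

    ``subject_ids`` restricts the computation to a subset (e.g. an age
    quartile); by default all results are pooled.
    """
    if subject_ids is not None:
        keep = set(subject_ids)
        results = [r for r in results if r.subject_id in keep]
    if not results:
        raise ConfigurationError("empty subject subset")
    strategy = results[0].strategy
    masks = []
    for r in results:
        di = np.flatnonzero(np.isclose(r.densities, density))
        if len(di) == 0:
            raise ConfigurationError(f"density {density} not in the computed grid")
        masks.append(r.prefail_majority[di[0]])
    freq = np.mean(masks, axis=0)
    return RemovalFrequencyMap(density=float(density), strategy=strategy, frequencies=freq)


class AttackSimulator:
    """Transformer from connectomes to percolation functions.

    scikit-learn-style wrapper over :func:`run_attacks`; ``transform``
    accepts a single :class:`Connectome` or a list and derives one child
    seed per subject from ``seed`` so results are order-independent.
    """

    def __init__(
        self,
        strategy: str = "random",
        densities: np.ndarray | None = None,
        n_iter: int = 100,
        seed: int = 0,
    ):
        self.strategy = strategy
        self.densities = densities
        self.n_iter = n_iter
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "strategy": self.strategy,
            "densities": self.densities,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "AttackSimulator":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "AttackSimulator":
        return self

    def transform(self, X: Connectome | list[Connectome]):
        densities = self.densities if self.densities is not None else default_density_grid()
        if isinstance(X, Connectome):
            X = [X]
            single = True
        else:
            single = False
        seeds = np.random.SeedSequence(self.seed).spawn(len(X))
        out = []
        for conn, ss in zip(X, seeds):
            cfg = AttackConfig(
                strategy=self.strategy,
                densities=np.asarray(densities, dtype=float),
                n_iter=self.n_iter,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            out.append(run_attacks(conn, cfg))
        return out[0] if single else out

    def fit_transform(self, X, y=None):
        return self.transform(X)
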