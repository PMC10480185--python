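"""Interaction topologies and synthetic inputs.

Provides the mean-field complete graph used in the main experiments, arbitrary
undirected graphs read from plain-text files, and seeded generators for uniform
initial opinions, the named media landscapes, per-agent confidence bounds, and a
two-community polarized network emulating an empirically observed two-faction
(pro/against) discussion snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import MediaLandscape

__all__ = [
    "InteractionGraph",
    "NodeAttributes",
    "uniform_initial_opinions",
    "scenario_media",
    "SCENARIOS",
    "polarized_network",
    "heterogeneous_epsilon_assignment",
    "read_graph",
]

# Named media landscapes from the mean-field experimental design.
SCENARIOS = {
    "moderate": (0.5,),
    "extremist": (0.0,),
    "polarized": (0.05, 0.95),
    "balanced": (0.05, 0.5, 0.95),
}


@dataclass
class InteractionGraph:
    """Simple undirected interaction graph over nodes ``0 .. n-1``.

    ``mean_field=True`` marks the complete graph without materialized edges; the
    simulation core takes a fast path for it.
    """

    n_nodes: int
    mean_field: bool = False
    adjacency: list | None = None  # list of sorted int arrays, one per node

    @classmethod
    def complete(cls, n: int) -> "InteractionGraph":
        if n < 2:
            raise ValueError("a complete interaction graph needs n >= 2")
        return cls(n_nodes=n, mean_field=True)

    @classmethod
    def from_edges(cls, n: int, edges) -> "InteractionGraph":
        """Build from an iterable of (u, v) pairs; duplicates collapse, self-loops
        are dropped."""
        adj: list[set] = [set() for _ in range(n)]
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) references a node outside 0..{n - 1}")
            if u == v:
                continue
            adj[u].add(v)
            adj[v].add(u)
        arrays = [np.array(sorted(s), dtype=np.int64) for s in adj]
        return cls(n_nodes=n, mean_field=False, adjacency=arrays)

    @classmethod
    def from_networkx(cls, g) -> "InteractionGraph":
        nodes = sorted(g.nodes())
        index = {u: k for k, u in enumerate(nodes)}
        return cls.from_edges(len(nodes), ((index[u], index[v]) for u, v in g.edges()))

    def neighbors(self, i: int) -> np.ndarray:
        if self.mean_field:
            idx = np.arange(self.n_nodes, dtype=np.int64)
            return np.delete(idx, i)
        return self.adjacency[i]

    @property
    def n_edges(self) -> int:
        if self.mean_field:
            return self.n_nodes * (self.n_nodes - 1) // 2
        return sum(a.size for a in self.adjacency) // 2

    def accessor(self):
        """Adjacency accessor for the simulation core (None = mean-field)."""
        if self.mean_field:
            return None
        return self.neighbors

    def to_networkx(self):
        import networkx as nx

        if self.mean_field:
            return nx.complete_graph(self.n_nodes)
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for u, nbrs in enumerate(self.adjacency):
            g.add_edges_from((u, int(v)) for v in nbrs if v > u)
        return g


@dataclass
class NodeAttributes:
    """Per-node initial opinions plus optional confidence bounds and labels.

    ``node_ids`` preserves the original (possibly string) identifiers of nodes
    loaded from files, in index order.
    """

    opinions: np.ndarray
    epsilon: np.ndarray | None = None
    labels: list | None = None
    node_ids: list | None = None

    def __post_init__(self) -> None:
        self.opinions = np.asarray(self.opinions, dtype=np.float64)
        if self.opinions.min() < 0.0 or self.opinions.max() > 1.0:
            raise ValueError("node opinions must lie in [0, 1]")
        if self.epsilon is not None:
            self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
            if self.epsilon.size != self.opinions.size:
                raise ValueError("epsilon length must match the number of nodes")

    @property
    def n(self) -> int:
        return self.opinions.size


def uniform_initial_opinions(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent opinions uniform on [0, 1] (the standard initial
    condition of the mean-field experiments)."""
    if n < 2:
        raise ValueError("need at least 2 agents")
    return rng.random(n)


def scenario_media(name: str) -> MediaLandscape:
    """Named media landscape: moderate (0.5), extremist (0.0),
    polarized (0.05, 0.95) or balanced (0.05, 0.5, 0.95)."""
    try:
        return MediaLandscape(SCENARIOS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
        ) from None


def polarized_network(
    n: int,
    intra_p: float,
    inter_p: float,
    means: tuple[float, float] = (0.28, 0.87),
    spread: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[InteractionGraph, NodeAttributes]:
    """Two equal communities with dense intra- and sparse inter-community edges.

    Each node's opinion is drawn from a normal around its community mean,
    truncated to [0, 1]. The default means (0.28, 0.87) mirror the average
    leanings of the pro and against factions in the two-community discussion
    network this fixture stands in for.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0.0 <= inter_p <= 1.0 and 0.0 < intra_p <= 1.0):
        raise ValueError("intra_p must be in (0, 1] and inter_p in [0, 1]")
    if intra_p < inter_p:
        raise ValueError("need intra_p >= inter_p for a community structure")
    for m in means:
        if not 0.0 <= m <= 1.0:
            raise ValueError("community means must lie in [0, 1]")
    half = n // 2
    block = np.zeros(n, dtype=np.int64)
    block[half:] = 1
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], intra_p, inter_p)
    keep = rng.random(p.size) < p
    graph = InteractionGraph.from_edges(n, zip(iu[keep], ju[keep]))
    if graph.n_edges == 0 or any(graph.neighbors(i).size == 0 for i in range(n)):
        warnings.warn("polarized_network produced isolated nodes or no edges")
    opinions = np.empty(n)
    for b, mean in enumerate(means):
        size = int(np.sum(block == b))
        a, bnd = (0.0 - mean) / spread, (1.0 - mean) / spread
        opinions[block == b] = stats.truncnorm.rvs(
            a, bnd, loc=mean, scale=spread, size=size, random_state=rng
        )
    labels = ["Pro" if b == 0 else "Against" for b in block]
    return graph, NodeAttributes(opinions=opinions, labels=labels)


def heterogeneous_epsilon_assignment(
    n: int, spec: dict, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-agent confidence bounds from a distribution description.

    ``spec`` is one of ``{"kind": "constant", "value": v}``,
    ``{"kind": "uniform", "low": a, "high": b}`` or
    ``{"kind": "beta", "a": a, "b": b}``; the support must lie inside [0, 1].
    Stands in for bounds estimated per user from data.
    """
    kind = spec.get("kind")
    if kind == "constant":
        v = float(spec["value"])
        if not 0.0 <= v <= 1.0:
            raise ValueError("constant epsilon must lie in [0, 1]")
        return np.full(n, v)
    if kind == "uniform":
        low, high = float(spec["low"]), float(spec["high"])
        if not (0.0 <= low <= high <= 1.0):
            raise ValueError("uniform epsilon support must lie inside [0, 1]")
        return rng.uniform(low, high, size=n)
    if kind == "beta":
        return rng.beta(float(spec["a"]), float(spec["b"]), size=n)
    raise ValueError(f"unknown epsilon spec kind {kind!r}")


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_graph(edge_list_path, attribute_table_path) -> tuple[InteractionGraph, NodeAttributes]:
    """Load an undirected simple graph plus node attributes from delimited text.

    The attribute table has columns ``node_id opinion [epsilon] [label]``
    (whitespace- or comma-separated; an optional header line starting with
    ``node_id`` is skipped). The edge list has two columns of node ids (optional
    ``source target`` header). Duplicate edges collapse; self-loops are dropped;
    malformed rows raise errors carrying the offending line number.
    """
    ids: list[str] = []
    index: dict[str, int] = {}
    opinions: list[float] = []
    epsilons: list[float] = []
    labels: list[str] = []
    with open(attribute_table_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = _tokenize(raw)
            if not tokens or raw.lstrip().startswith("#"):
                continue
            if lineno == 1 and tokens[0].lower() == "node_id":
                continue
            if len(tokens) < 2:
                raise ValueError(
                    f"{attribute_table_path}:{lineno}: expected at least node_id and opinion"
                )
            node_id = tokens[0]
            if node_id in index:
                raise ValueError(f"{attribute_table_path}:{lineno}: duplicate node id {node_id!r}")
            try:
                opinion = float(tokens[1])
            except ValueError:
                raise ValueError(
                    f"{attribute_table_path}:{lineno}: opinion {tokens[1]!r} is not a number"
                ) from None
            if not 0.0 <= opinion <= 1.0:
                raise ValueError(
                    f"{attribute_table_path}:{lineno}: opinion {opinion} outside [0, 1]"
                )
            eps = None
            label = None
            rest = tokens[2:]
            if rest:
                try:
                    eps = float(rest[0])
                    rest = rest[1:]
                except ValueError:
                    pass
                if rest:
                    label = rest[0]
            if eps is not None and not 0.0 <= eps <= 1.0:
                raise ValueError(
                    f"{attribute_table_path}:{lineno}: epsilon {eps} outside [0, 1]"
                )
            index[node_id] = len(ids)
            ids.append(node_id)
            opinions.append(opinion)
            epsilons.append(eps if eps is not None else np.nan)
            labels.append(label)

    if not ids:
        raise ValueError(f"{attribute_table_path}: no node rows found")

    edges = []
    dropped_loops = 0
    with open(edge_list_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = _tokenize(raw)
            if not tokens or raw.lstrip().startswith("#"):
                continue
            if lineno == 1 and [t.lower() for t in tokens[:2]] == ["source", "target"]:
                continue
            if len(tokens) != 2:
                raise ValueError(
                    f"{edge_list_path}:{lineno}: expected two columns, got {len(tokens)}"
                )
            u, v = tokens
            for t in (u, v):
                if t not in index:
                    raise ValueError(f"{edge_list_path}:{lineno}: unknown node id {t!r}")
            if u == v:
                dropped_loops += 1
                continue
            edges.append((index[u], index[v]))
    if dropped_loops:
        warnings.warn(f"{edge_list_path}: dropped {dropped_loops} self-loop(s)")

    graph = InteractionGraph.from_edges(len(ids), edges)
    eps_arr = np.asarray(epsilons)
    attrs = NodeAttributes(
        opinions=np.asarray(opinions),
        epsilon=None if np.isnan(eps_arr).all() else eps_arr,
        labels=None if all(l is None for l in labels) else labels,
        node_ids=ids,
    )
    return graph, attrs
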