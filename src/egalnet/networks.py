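"""Construction of the five network treatments.

Five fixed topologies on a common income profile: a fully saturated
network, two 4-regular ring lattices differing in how incomes are
assorted (homophilous vs heterophilous), and two scale-free networks
differing in the sign of the degree-income association. The four
non-full networks share the same edge count so that treatment effects
reflect structure, not tie volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

#: The five treatment labels, in canonical order.
LABELS = ("Full", "Lattice_Hetero", "Lattice_Homo", "SF_Negative", "SF_Positive")

Edge = tuple[int, int]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _normalize_edges(edges: Iterable[Sequence[int]]) -> tuple[Edge, ...]:
    out: set[Edge] = set()
    for u, v in edges:
        u, v = int(u), int(v)
        if u == v:
            raise ValueError(f"self-loop on node {u}")
        out.add((u, v) if u < v else (v, u))
    return tuple(sorted(out))


@dataclass
class Topology:
    """A labeled, connected, simple undirected graph with initial incomes.

    Node ids are 0-based consecutive integers; edges are stored with the
    smaller id first. ``income_0`` holds each node's initial token count.
    """

    label: str
    n: int
    edges: tuple[Edge, ...]
    income_0: tuple[int, ...]
    _adj: dict[int, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = _normalize_edges(self.edges)
        self.income_0 = tuple(int(x) for x in self.income_0)
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown treatment label {self.label!r}")
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if len(self.income_0) != self.n:
            raise ValueError("income_0 length must equal n")
        if any(x <= 0 for x in self.income_0):
            raise ValueError("initial incomes must be positive integers")
        nodes = {u for e in self.edges for u in e}
        if nodes - set(range(self.n)):
            raise ValueError("edge endpoints outside 0..n-1")
        g = nx.Graph(self.edges)
        g.add_nodes_from(range(self.n))
        if not nx.is_connected(g):
            raise ValueError("graph must be connected")
        deg = self.degrees()
        if self.label == "Full" and len(self.edges) != self.n * (self.n - 1) // 2:
            raise ValueError("Full label requires all pairs present")
        if self.label.startswith("Lattice"):
            # ring lattices are even-degree regular (k=4 in the standard profile)
            if deg.min() != deg.max() or deg[0] % 2:
                raise ValueError("Lattice labels require an even-degree regular graph")

    # -- derived structure ------------------------------------------------

    def graph(self) -> nx.Graph:
        g = nx.Graph(self.edges)
        g.add_nodes_from(range(self.n))
        return g

    def adjacency(self) -> dict[int, np.ndarray]:
        if self._adj is None:
            lists: dict[int, list[int]] = {i: [] for i in range(self.n)}
            for u, v in self.edges:
                lists[u].append(v)
                lists[v].append(u)
            self._adj = {i: np.array(sorted(js), dtype=int) for i, js in lists.items()}
        return self._adj

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency()[int(i)]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "n": self.n,
                "edges": [list(e) for e in self.edges],
                "income_0": list(self.income_0),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Topology":
        doc = json.loads(text)
        return cls(doc["label"], int(doc["n"]), doc["edges"], doc["income_0"])

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u} {v}\n")


def read_edgelist(path) -> tuple[Edge, ...]:
    """Read a plain-text 'u v' edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
    return _normalize_edges(edges)


# -- generators -----------------------------------------------------------


def generate_incomes(n: int, lo: int = 10, hi: int = 200) -> np.ndarray:
    """Evenly spaced integer income profile pinned at ``lo`` and ``hi``.

    Interior values are ``lo + i*(hi-lo)/(n-1)`` rounded to the nearest
    integer; the endpoints are exact. The standard profile is n=25,
    10..200 tokens.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if lo >= hi:
        raise ValueError("need lo < hi")
    vals = np.rint(lo + np.arange(n) * (hi - lo) / (n - 1)).astype(int)
    vals[0], vals[-1] = lo, hi
    return vals


def make_ring_lattice(n: int, k: int = 4) -> tuple[Edge, ...]:
    """Ring lattice: each node tied to its k/2 nearest neighbors per side."""
    if k % 2 or k < 2:
        raise ValueError("k must be a positive even integer")
    if k >= n:
        raise ValueError("need k < n")
    edges = []
    for i in range(n):
        for d in range(1, k // 2 + 1):
            edges.append((i, (i + d) % n))
    return _normalize_edges(edges)


def make_full(n: int) -> tuple[Edge, ...]:
    """All n(n-1)/2 pairs: everyone linked to all others."""
    if n < 2:
        raise ValueError("need n >= 2")
    return tuple((u, v) for u in range(n) for v in range(u + 1, n))


def make_scale_free(
    n: int, m_edges: int, rng: np.random.Generator | int | None = None
) -> tuple[Edge, ...]:
    """Connected preferential-attachment graph with exactly ``m_edges`` edges.

    Grown Barabasi-Albert style from a small seed clique (each new node
    attaches to ``m`` existing nodes with probability proportional to
    degree), then topped up with additional preferentially sampled
    non-duplicate edges until the exact target edge count is reached, so
    the density can be matched to a k-regular lattice on the same nodes.
    """
    rng = _as_rng(rng)
    if not (n - 1 <= m_edges <= n * (n - 1) // 2):
        raise ValueError("m_edges out of range for a connected simple graph")
    # largest growth attachment count in {1, 2} that fits the edge budget
    m = 1
    if n >= 3 and 3 + 2 * (n - 3) <= m_edges:
        m = 2
    adj: list[set[int]] = [set() for _ in range(n)]
    deg = np.zeros(n, dtype=float)

    def add_edge(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)
        deg[u] += 1
        deg[v] += 1

    n_seed = m + 1
    for u in range(n_seed):
        for v in range(u + 1, n_seed):
            add_edge(u, v)
    for new in range(n_seed, n):
        targets: set[int] = set()
        while len(targets) < m:
            p = deg[:new] / deg[:new].sum()
            t = int(rng.choice(new, p=p))
            targets.add(t)
        for t in targets:
            add_edge(new, t)
    n_current = int(deg.sum()) // 2
    while n_current < m_edges:
        p = deg / deg.sum()
        u = int(rng.choice(n, p=p))
        candidates = np.array(
            [v for v in range(n) if v != u and v not in adj[u]], dtype=int
        )
        if candidates.size == 0:
            continue
        w = deg[candidates] / deg[candidates].sum()
        v = int(rng.choice(candidates, p=w))
        add_edge(u, v)
        n_current += 1
    return _normalize_edges(
        (u, v) for u in range(n) for v in adj[u] if u < v
    )


# -- income placement -----------------------------------------------------


def place_incomes_lattice(
    edges: tuple[Edge, ...], incomes: Sequence[int], mode: str
) -> Topology:
    """Assort incomes around a ring lattice.

    ``homophilous``: sorted incomes laid out in circular order, so
    neighbors hold adjacent ranks. ``heterophilous``: ranks interleaved
    by alternating draws from the low and high ends of the sorted list,
    so neighbors hold strongly contrasting incomes.
    """
    incomes = [int(x) for x in incomes]
    n = len(incomes)
    if {u for e in edges for u in e} != set(range(n)):
        raise ValueError("income vector length must match node count")
    s = sorted(incomes)
    if mode == "homophilous":
        placed = s
        label = "Lattice_Homo"
    elif mode == "heterophilous":
        placed = []
        lo, hi = 0, n - 1
        while lo <= hi:
            placed.append(s[lo])
            lo += 1
            if lo <= hi:
                placed.append(s[hi])
                hi -= 1
        label = "Lattice_Hetero"
    else:
        raise ValueError("mode must be 'homophilous' or 'heterophilous'")
    return Topology(label, n, edges, tuple(placed))


def place_incomes_sf(
    edges: tuple[Edge, ...], incomes: Sequence[int], direction: str
) -> Topology:
    """Rank-match incomes to degree on a scale-free graph.

    ``positive``: i-th largest income on the i-th highest-degree node
    (degree ties broken by node id); ``negative``: reversed.
    """
    incomes = [int(x) for x in incomes]
    n = len(incomes)
    nodes = {u for e in edges for u in e}
    if nodes != set(range(n)):
        raise ValueError("income vector length must match node count")
    deg = np.zeros(n, dtype=int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    by_degree = sorted(range(n), key=lambda i: (-deg[i], i))
    if direction == "positive":
        ordered = sorted(incomes, reverse=True)
        label = "SF_Positive"
    elif direction == "negative":
        ordered = sorted(incomes)
        label = "SF_Negative"
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    placed = [0] * n
    for node, inc in zip(by_degree, ordered):
        placed[node] = inc
    return Topology(label, n, edges, tuple(placed))


def standard_treatments(
    n: int = 25,
    lo: int = 10,
    hi: int = 200,
    rng: np.random.Generator | int | None = None,
    k: int = 4,
) -> dict[str, Topology]:
    """Build all five treatments on a shared income profile.

    The two lattices are k-regular rings; the two scale-free graphs are
    drawn independently and constrained to the lattice edge count nk/2,
    so all four non-full treatments are density-matched.
    """
    rng = _as_rng(rng)
    incomes = generate_incomes(n, lo, hi)
    ring = make_ring_lattice(n, k)
    m_edges = n * k // 2
    topo = {
        "Full": Topology("Full", n, make_full(n), tuple(incomes)),
        "Lattice_Hetero": place_incomes_lattice(ring, incomes, "heterophilous"),
        "Lattice_Homo": place_incomes_lattice(ring, incomes, "homophilous"),
        "SF_Negative": place_incomes_sf(make_scale_free(n, m_edges, rng), incomes, "negative"),
        "SF_Positive": place_incomes_sf(make_scale_free(n, m_edges, rng), incomes, "positive"),
    }
    return topo
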