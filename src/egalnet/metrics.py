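"""Inequality and network-position metrics.

Global Gini coefficient (population form), local neighborhood Gini L,
normalized income ranking R, and nodal degree K — the four covariates
that drive giving decisions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .networks import Topology


def gini(values) -> float:
    """Population Gini: mean absolute pairwise difference over twice the mean.

    Uses the sorted-order identity G = 2*sum(i*x_(i))/(n*sum(x)) - (n+1)/n,
    equivalent to the O(n^2) double sum over all ordered pairs. No
    small-sample correction is applied, so the local Gini of a fully
    connected neighborhood equals the global Gini exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("incomes must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("need a positive total")
    n = x.size
    xs = np.sort(x)
    return float(2.0 * np.arange(1, n + 1).dot(xs) / (n * total) - (n + 1) / n)


def local_inequality(topology: Topology, incomes, i: int) -> float:
    """Gini of the incomes of actor i and its network neighbors."""
    incomes = np.asarray(incomes, dtype=float)
    nbrs = topology.neighbors(i)
    if nbrs.size == 0:
        raise ValueError(f"node {i} is isolated")
    return gini(np.concatenate(([incomes[i]], incomes[nbrs])))


def income_ranking(topology: Topology, incomes, i: int) -> float:
    """Actor i's normalized position in the low-to-high income ordering
    of self plus neighbors (average rank under ties, divided by the
    sequence length), so R lies in (0, 1]."""
    incomes = np.asarray(incomes, dtype=float)
    nbrs = topology.neighbors(i)
    if nbrs.size == 0:
        raise ValueError(f"node {i} is isolated")
    seq = np.concatenate(([incomes[i]], incomes[nbrs]))
    return float(rankdata(seq)[0] / seq.size)


class _FeatureCache:
    """Padded neighborhood index matrix for vectorized per-round features."""

    def __init__(self, topology: Topology):
        adj = topology.adjacency()
        n = topology.n
        deg = np.array([adj[i].size for i in range(n)])
        width = int(deg.max()) + 1  # self + neighbors
        idx = np.zeros((n, width), dtype=int)
        mask = np.zeros((n, width), dtype=bool)
        for i in range(n):
            idx[i, 0] = i
            idx[i, 1 : 1 + deg[i]] = adj[i]
            mask[i, : 1 + deg[i]] = True
        self.idx, self.mask, self.deg, self.m = idx, mask, deg, deg + 1.0


_caches: dict[int, tuple[Topology, _FeatureCache]] = {}


def _cache_for(topology: Topology) -> _FeatureCache:
    key = id(topology)
    hit = _caches.get(key)
    if hit is None or hit[0] is not topology:
        _caches[key] = (topology, _FeatureCache(topology))
    return _caches[key][1]


def agent_features(topology: Topology, incomes) -> dict[str, np.ndarray]:
    """Per-agent X (income), R (normalized rank), L (local Gini), K (degree),
    all computed from the same income snapshot. Vectorized over agents."""
    x = np.asarray(incomes, dtype=float)
    c = _cache_for(topology)
    nb = np.where(c.mask, x[c.idx], np.nan)  # row i = self + neighbors of i
    m = c.m
    # normalized average rank of the self entry within its row
    own = nb[:, :1]
    less = np.nansum(nb < own, axis=1)
    equal = np.nansum(nb == own, axis=1)
    r = (less + (equal + 1) / 2.0) / m
    # rowwise population Gini; nan padding sorts last and is excluded by m
    srt = np.sort(nb, axis=1)
    ranks = np.arange(1, nb.shape[1] + 1, dtype=float)
    totals = np.nansum(nb, axis=1)
    weighted = np.nansum(srt * ranks, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        l = 2.0 * weighted / (m * totals) - (m + 1) / m
    l = np.where(totals > 0, l, 0.0)
    return {
        "X": np.asarray(incomes).copy(),
        "R": r,
        "L": np.maximum(l, 0.0),
        "K": c.deg.copy(),
    }
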