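"""Weighted clique percolation (CPMw) assignment of individuals to groups.

A community is the union of adjacent k-cliques — cliques sharing k-1
nodes — among the k-cliques whose intensity (the geometric mean of their
edge weights) reaches a threshold.  Individuals covered by no retained
clique are classed as solitary.  Because communities can overlap, a
disjoint assignment (needed for group-level statistics) places each
shared individual in the community where its within-community strength
is largest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, DegenerateInputError

__all__ = [
    "CommunityAssignment",
    "enumerate_k_cliques",
    "clique_intensity",
    "cpmw_communities",
    "select_threshold",
    "disjoint_assignment",
    "NoCliquesError",
]


class NoCliquesError(DegenerateInputError):
    """The graph contains no k-clique; callers should fall back to components."""


@dataclass
class CommunityAssignment:
    communities: list[frozenset]
    solitary: frozenset
    k: int
    intensity_threshold: float

    def membership(self) -> dict:
        """Node -> list of community indices (possibly several: overlap)."""
        out: dict = {}
        for ci, comm in enumerate(self.communities):
            for node in comm:
                out.setdefault(node, []).append(ci)
        for node in self.solitary:
            out.setdefault(node, [])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, comms in sorted(self.membership().items(), key=lambda kv: str(kv[0])):
            if comms:
                for ci in comms:
                    rows.append({"individual_id": node, "community_id": ci, "solitary": False})
            else:
                rows.append({"individual_id": node, "community_id": -1, "solitary": True})
        return pd.DataFrame(rows, columns=["individual_id", "community_id", "solitary"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_k_cliques(graph: nx.Graph, k: int) -> list[frozenset]:
    """All complete k-subsets of the graph, each exactly once.

    Enumerated by expanding maximal cliques (Bron–Kerbosch with
    pivoting via networkx) into their k-subsets; adequate for the small
    group networks this package targets.
    """
    if k < 3:
        raise ConfigError(f"clique percolation requires k >= 3, got {k}")
    seen: set[frozenset] = set()
    for maximal in nx.find_cliques(graph):
        if len(maximal) < k:
            continue
        for subset in itertools.combinations(sorted(maximal, key=str), k):
            seen.add(frozenset(subset))
    return sorted(seen, key=lambda c: tuple(sorted(map(str, c))))


def clique_intensity(clique: Iterable, graph: nx.Graph) -> float:
    """Geometric mean of the clique's edge weights: (prod w)^(2 / (k(k-1)))."""
    nodes = list(clique)
    k = len(nodes)
    prod = 1.0
    n_edges = 0
    for a, b in itertools.combinations(nodes, 2):
        if not graph.has_edge(a, b):
            raise ConsistencyError(f"clique edge ({a}, {b}) missing from graph")
        prod *= graph[a][b].get("weight", 1.0)
        n_edges += 1
    assert n_edges == k * (k - 1) // 2
    return prod ** (1.0 / n_edges)


def _cliques_with_intensity(graph: nx.Graph, k: int) -> list[tuple[frozenset, float]]:
    return [(c, clique_intensity(c, graph)) for c in enumerate_k_cliques(graph, k)]


def _percolate(cliques: Sequence[frozenset], k: int) -> list[frozenset]:
    """Communities = node unions of connected components of the clique graph."""
    # union-find over cliques keyed by shared (k-1)-subsets
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    sub_index: dict[frozenset, int] = {}
    for ci, clique in enumerate(cliques):
        for sub in itertools.combinations(sorted(clique, key=str), k - 1):
            key = frozenset(sub)
            if key in sub_index:
                union(ci, sub_index[key])
            else:
                sub_index[key] = ci

    comps: dict[int, set] = {}
    for ci, clique in enumerate(cliques):
        comps.setdefault(find(ci), set()).update(clique)
    return sorted(
        (frozenset(c) for c in comps.values()),
        key=lambda c: (-len(c), tuple(sorted(map(str, c)))),
    )


def cpmw_communities(
    graph: nx.Graph,
    k: int = 3,
    intensity_threshold: float = 0.0,
) -> CommunityAssignment:
    """Weighted clique percolation at a fixed intensity threshold.

    Cliques with intensity >= threshold are kept; two kept cliques are
    adjacent when they share k-1 nodes; communities are the node unions
    of connected clique components.  Nodes in no community are solitary.
    """
    if intensity_threshold < 0:
        raise ConfigError("intensity threshold must be >= 0")
    kept = [c for c, w in _cliques_with_intensity(graph, k) if w >= intensity_threshold]
    communities = _percolate(kept, k)
    covered = set().union(*communities) if communities else set()
    solitary = frozenset(set(graph.nodes) - covered)
    return CommunityAssignment(
        communities=list(communities),
        solitary=solitary,
        k=k,
        intensity_threshold=intensity_threshold,
    )


def select_threshold(
    graph: nx.Graph,
    k: int = 3,
    strategy: str = "critical",
    fraction: float = 0.5,
    max_candidates: int = 40,
) -> float:
    """Pick an intensity threshold just below the percolation critical point.

    The default strategy scans candidate thresholds taken from the
    sorted distinct clique intensities (thinned to at most
    ``max_candidates`` quantiles on large graphs) and returns the
    largest threshold at which the largest community still contains at
    least ``fraction`` of all clique-covered nodes.  Raises
    :class:`NoCliquesError` when the graph has no k-clique, in which
    case callers should treat each connected component as a community.
    """
    if graph.number_of_nodes() == 0:
        raise NoCliquesError("empty graph")
    if strategy != "critical":
        raise ConfigError(f"unknown threshold strategy {strategy!r}")
    pairs = _cliques_with_intensity(graph, k)
    if not pairs:
        raise NoCliquesError(f"graph has no {k}-clique")
    intensities = sorted({w for _, w in pairs})
    if len(intensities) > max_candidates:
        picks = np.linspace(0, len(intensities) - 1, max_candidates).round().astype(int)
        intensities = [intensities[i] for i in sorted(set(picks.tolist()))]
    covered = set().union(*(c for c, _ in pairs))
    best = intensities[0]
    for t in intensities:
        kept = [c for c, w in pairs if w >= t]
        communities = _percolate(kept, k)
        largest = max((len(c) for c in communities), default=0)
        if largest >= fraction * len(covered):
            best = t
    return best


def disjoint_assignment(
    assignment: CommunityAssignment,
    graph: nx.Graph,
) -> dict:
    """Resolve overlapping memberships into one community per individual.

    An individual in several communities is assigned to the one where
    the sum of its edge weights to co-members is largest; ties go to the
    larger community, then to the lexicographically first.  Returns
    node -> community index (-1 for solitary).
    """
    out: dict = {}
    for node, comms in assignment.membership().items():
        if not comms:
            out[node] = -1
        elif len(comms) == 1:
            out[node] = comms[0]
        else:
            def score(ci: int):
                members = assignment.communities[ci] - {node}
                w = sum(
                    graph[node][m].get("weight", 1.0)
                    for m in members
                    if graph.has_edge(node, m)
                )
                return (w, len(assignment.communities[ci]), -ci)

            out[node] = max(comms, key=score)
    return out
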