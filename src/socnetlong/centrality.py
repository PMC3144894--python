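"""The seven network measures used in the longevity analysis.

Individual measures: strength centrality (weighted degree), Bonacich
power, and Stephenson–Zelen information centrality.  Group measures:
the within-group standard deviation of each individual measure,
distance-based cohesion (compactness), and Freeman-style network
centralization adapted to weighted graphs.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .community import CommunityAssignment, disjoint_assignment
from .errors import ConfigError, DegenerateInputError, DomainError

__all__ = [
    "strength",
    "bonacich_power",
    "information_centrality",
    "group_dispersion",
    "cohesion",
    "centralization",
    "centrality_table",
]


def _weight_matrix(graph: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = sorted(graph.nodes, key=str)
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return nodes, w


def strength(graph: nx.Graph) -> dict:
    """Weighted degree: s_i = sum_j w_ij."""
    if graph.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    nodes, w = _weight_matrix(graph)
    return dict(zip(nodes, w.sum(axis=1)))


def bonacich_power(
    graph: nx.Graph,
    beta: float | None = None,
    normalize: bool = True,
) -> dict:
    """Bonacich power centrality c = (I - beta*W)^-1 W 1.

    ``beta`` weights the contribution of a node's neighbours'
    connectedness and must satisfy |beta| < 1/rho(W) for the defining
    power series to converge; the default is 0.5/rho(W).  With
    ``normalize`` the vector is scaled so that sum(c^2) = n (the
    conventional alpha); beta = 0 recovers strength centrality.
    """
    nodes, w = _weight_matrix(graph)
    n = len(nodes)
    rho = float(np.max(np.abs(np.linalg.eigvalsh(w)))) if n else 0.0
    if beta is None:
        beta = 0.5 / rho if rho > 0 else 0.0
    if rho > 0 and abs(beta) >= 1.0 / rho:
        raise DomainError(
            f"|beta| must be < 1/spectral radius = {1.0 / rho:.6g}, got {beta}"
        )
    ones = np.ones(n)
    c = np.linalg.solve(np.eye(n) - beta * w, w @ ones)
    if normalize:
        norm = float(np.sqrt(c @ c))
        if norm > 0:
            c = c * np.sqrt(n) / norm
    return dict(zip(nodes, c))


def information_centrality(graph: nx.Graph, per_component: bool = False) -> dict:
    """Stephenson–Zelen information centrality (weights as conductances).

    With B = D - W + J (D the diagonal of strengths, J all-ones) and
    C = B^-1, node i's centrality is n / (n*C_ii + trace(C) - 2*rowsum_i(C)).
    Defined per connected component; a disconnected graph raises unless
    ``per_component`` is set.
    """
    if graph.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    if not nx.is_connected(graph):
        if not per_component:
            raise DomainError(
                "graph is disconnected; pass per_component=True to compute "
                "information centrality within each component"
            )
        out: dict = {}
        for comp in nx.connected_components(graph):
            out.update(information_centrality(graph.subgraph(comp).copy()))
        return out
    nodes, w = _weight_matrix(graph)
    n = len(nodes)
    if n == 1:
        return {nodes[0]: float("inf")}
    d = np.diag(w.sum(axis=1))
    b = d - w + np.ones((n, n))
    c = np.linalg.inv(b)
    t = np.trace(c)
    r = c.sum(axis=1)
    vals = n / (n * np.diag(c) + t - 2 * r)
    return dict(zip(nodes, vals))


def group_dispersion(
    values: Mapping,
    groups: CommunityAssignment | Mapping,
    graph: nx.Graph | None = None,
    estimator: str = "population",
) -> dict:
    """Per-group standard deviation of an individual centrality measure.

    ``groups`` is either a disjoint node -> group-id mapping or a
    :class:`CommunityAssignment` (resolved to disjoint membership via
    within-community strength; requires ``graph``).  Estimator
    "population" divides by n, "sample" by n-1 (undefined for
    singletons, which raise).
    """
    if estimator not in ("population", "sample"):
        raise ConfigError("estimator must be 'population' or 'sample'")
    if isinstance(groups, CommunityAssignment):
        if graph is None:
            raise ConfigError("resolving overlapping communities requires graph=")
        groups = disjoint_assignment(groups, graph)
    members: dict = {}
    for node, gid in groups.items():
        if gid == -1 or node not in values:
            continue
        members.setdefault(gid, []).append(values[node])
    out: dict = {}
    for gid, vals in members.items():
        if estimator == "sample" and len(vals) < 2:
            raise DegenerateInputError(
                f"sample SD undefined for singleton group {gid}"
            )
        ddof = 0 if estimator == "population" else 1
        out[gid] = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
    return out


def cohesion(graph: nx.Graph, distance_rule: str = "inverse_weight") -> float:
    """Distance-based cohesion (compactness) in [0, 1].

    The mean over ordered node pairs of the reciprocal shortest-path
    distance, with 1/d = 0 for unreachable pairs.  Distances use edge
    length 1/weight by default ("inverse_weight"); "binary" treats
    every edge as length 1.
    """
    if distance_rule not in ("binary", "inverse_weight"):
        raise ConfigError("distance_rule must be 'binary' or 'inverse_weight'")
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n < 2:
        raise DegenerateInputError("cohesion requires at least 2 nodes")
    if distance_rule == "binary":
        weight_attr = None
        g = graph
    else:
        g = graph.copy()
        for a, b, data in g.edges(data=True):
            w = data.get("weight", 1.0)
            if w <= 0:
                raise DomainError("inverse-weight distances require positive weights")
            data["length"] = 1.0 / w
        weight_attr = "length"
    total = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight=weight_attr))
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            d = lengths.get(i, {}).get(j)
            if d is not None and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def centralization(graph: nx.Graph) -> float:
    """Freeman-style strength centralization scaled to [0, 1].

    sum_i (s_max - s_i) / ((n-1)(n-2) w_max): 1 for a star with uniform
    weights, 0 for any weight-regular graph.  The w_max scaling makes
    the weighted statistic hit those anchors; absolute values depend on
    this normalization choice.
    """
    nodes, w = _weight_matrix(graph)
    n = len(nodes)
    if n < 3:
        raise DegenerateInputError("centralization requires at least 3 nodes")
    s = w.sum(axis=1)
    w_max = float(w.max())
    if w_max <= 0:
        return 0.0
    return float((s.max() - s).sum() / ((n - 1) * (n - 2) * w_max))


def centrality_table(
    graph: nx.Graph,
    assignment: CommunityAssignment,
    beta: float | None = None,
    estimator: str = "population",
    distance_rule: str = "inverse_weight",
    period: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual- and group-level measure tables for one network period.

    Returns ``(individual_frame, group_frame)``: the first holds
    strength, power and information centrality per individual with its
    (disjoint) group; the second the three group SDs plus cohesion,
    centralization and size per group, both computed on the group's
    induced subgraph.
    """
    s = strength(graph)
    p = bonacich_power(graph, beta=beta)
    info = information_centrality(graph, per_component=True)
    disjoint = disjoint_assignment(assignment, graph)

    ind = pd.DataFrame(
        {
            "period": period,
            "individual": sorted(graph.nodes, key=str),
        }
    )
    ind["group"] = [disjoint.get(i, -1) for i in ind["individual"]]
    ind["strength"] = [s[i] for i in ind["individual"]]
    ind["power"] = [p[i] for i in ind["individual"]]
    ind["information"] = [info[i] for i in ind["individual"]]

    rows = []
    for gid in sorted({g for g in disjoint.values() if g != -1}):
        members = [i for i, g in disjoint.items() if g == gid]
        sub = graph.subgraph(members)
        sub_s = strength(sub) if sub.number_of_nodes() else {}
        sub_p = bonacich_power(sub, beta=beta) if sub.number_of_nodes() else {}
        sub_i = information_centrality(sub, per_component=True) if sub.number_of_nodes() else {}
        gmap = {m: gid for m in members}
        ddofed = dict(
            sd_strength=group_dispersion(sub_s, gmap, estimator=estimator).get(gid, 0.0),
            sd_power=group_dispersion(sub_p, gmap, estimator=estimator).get(gid, 0.0),
            sd_information=group_dispersion(sub_i, gmap, estimator=estimator).get(gid, 0.0),
        )
        rows.append(
            {
                "period": period,
                "group": gid,
                **ddofed,
                "cohesion": cohesion(sub, distance_rule) if len(members) >= 2 else np.nan,
                "centralization": centralization(sub) if len(members) >= 3 else np.nan,
                "size": len(members),
            }
        )
    grp = pd.DataFrame(
        rows,
        columns=[
            "period", "group", "sd_strength", "sd_power", "sd_information",
            "cohesion", "centralization", "size",
        ],
    )
    return ind, grp
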