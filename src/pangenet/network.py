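"""Topology statistics for protein-protein interaction networks.

For a simple undirected graph the suite computes the three per-degree
profiles commonly used to classify interaction networks:

* degree distribution ``P(k) = n_k / N`` — fraction of nodes with degree k;
* per-degree clustering ``C(k)``, where a node's clustering coefficient is
  ``2E / [k(k-1)]`` for ``E`` edges among its k neighbors, averaged within
  each degree class;
* average neighborhood connectivity ``C_n(k_n)`` — the mean degree of the
  neighbors of degree-``k_n`` nodes, averaged within each degree class.

Each profile is summarised by an ordinary least-squares fit on log-log axes
(``y ~ x**-exponent``; the exponent is the negated slope).  The resulting
order parameters — gamma for P(k), beta for C(k), alpha for C_n(k_n) —
drive the classification: a small degree exponent (gamma < 2) with positive
beta and alpha marks a hierarchical scale-free network whose sparse
high-degree hubs control many low-degree nodes, while a negative alpha
(neighborhood connectivity *increasing* with degree) marks assortative
mixing.  Hubs default to nodes whose degree strictly exceeds the mean plus
two standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sp_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float      # positive order parameter; y ~ x**-exponent
    r_squared: float
    n_points: int
    n_dropped: int = 0   # non-positive points excluded from the log-log fit


@dataclass
class HubReport:
    ranking: list[tuple[str, int]]   # all nodes, by descending degree then id
    hubs: list[str]
    rule: str


@dataclass
class TopologyClassification:
    label: str       # hierarchical | scale_free_nonhierarchical | assortative | inconclusive
    rationale: list[str]


def load_edgelist(path: str | Path) -> nx.Graph:
    """Read a two-column (optionally scored) edge-list TSV into a simple graph.

    Self-loops and duplicate edges (including reversed duplicates, as in
    database exports that list both directions) are dropped with a warning.
    """
    graph = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            u, v = fields[0], fields[1]
            if u == v or graph.has_edge(u, v):
                dropped += 1
                continue
            graph.add_edge(u, v)
    if dropped:
        logger.warning("dropped %d self-loop/duplicate edges from %s", dropped, path)
    return graph


def _check_simple(graph: nx.Graph) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValueError(f"network has self-loops: {loops[:5]}")
    return graph


def degree_distribution(graph: nx.Graph) -> dict[int, float]:
    """``P(k) = n_k / N`` over the observed degrees; values sum to 1."""
    _check_simple(graph)
    n = graph.number_of_nodes()
    counts: dict[int, int] = {}
    for _, k in graph.degree():
        counts[k] = counts.get(k, 0) + 1
    return {k: counts[k] / n for k in sorted(counts)}


def node_clustering(graph: nx.Graph, node) -> float:
    """Clustering coefficient 2E/[k(k-1)] of one node (k >= 2 required)."""
    neighbors = list(graph[node])
    k = len(neighbors)
    if k < 2:
        raise ValueError("clustering coefficient is undefined for degree < 2")
    e = 0
    for i in range(k):
        adjacency = graph[neighbors[i]]
        for j in range(i + 1, k):
            if neighbors[j] in adjacency:
                e += 1
    return 2.0 * e / (k * (k - 1))


def clustering_profile(graph: nx.Graph) -> dict[int, float]:
    """Mean clustering coefficient per degree class (degree >= 2 only)."""
    _check_simple(graph)
    by_degree: dict[int, list[float]] = {}
    for node, k in graph.degree():
        if k < 2:
            continue
        by_degree.setdefault(k, []).append(node_clustering(graph, node))
    return {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}


def neighborhood_connectivity(graph: nx.Graph) -> dict[int, float]:
    """Mean neighbor degree per degree class; isolated nodes are skipped."""
    _check_simple(graph)
    isolated = [n for n, k in graph.degree() if k == 0]
    if isolated:
        logger.warning("skipping %d isolated nodes in neighborhood connectivity", len(isolated))
    by_degree: dict[int, list[float]] = {}
    for node, k in graph.degree():
        if k == 0:
            continue
        mean_neighbor_degree = float(np.mean([graph.degree(m) for m in graph[node]]))
        by_degree.setdefault(k, []).append(mean_neighbor_degree)
    return {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}


def power_law_fit(points: dict[float, float], min_points: int = 3) -> PowerLawFit:
    """OLS fit of ``log10 y`` on ``log10 x``; exponent = -slope.

    Points with non-positive x or y are excluded (log undefined) and counted
    in ``n_dropped``.  A constant profile fits exponent 0 exactly.
    """
    xs = np.array([x for x, y in points.items() if x > 0 and y > 0], dtype=float)
    ys = np.array([y for x, y in points.items() if x > 0 and y > 0], dtype=float)
    dropped = len(points) - len(xs)
    if len(xs) < min_points:
        raise ValueError(f"power-law fit needs >= {min_points} positive points, got {len(xs)}")
    if np.ptp(ys) == 0:
        return PowerLawFit(exponent=0.0, r_squared=1.0, n_points=len(xs), n_dropped=dropped)
    result = sp_stats.linregress(np.log10(xs), np.log10(ys))
    return PowerLawFit(
        exponent=float(-result.slope),
        r_squared=float(result.rvalue**2),
        n_points=len(xs),
        n_dropped=dropped,
    )


def identify_hubs(graph: nx.Graph, rule: str = "sigma", top_n: int = 5) -> HubReport:
    """Rank nodes by degree and select hubs.

    ``rule="sigma"``: hubs are nodes whose degree strictly exceeds
    ``mean + 2 * SD`` of the degree sequence (population SD; a regular graph
    therefore has no hubs).  ``rule="top_n"``: the ``top_n`` highest-degree
    nodes.  Ranking ties break lexicographically on the node id.
    """
    _check_simple(graph)
    if graph.number_of_nodes() < 2:
        raise ValueError("hub identification needs at least two nodes")
    degrees = dict(graph.degree())
    ranking = sorted(degrees.items(), key=lambda item: (-item[1], str(item[0])))
    ranking = [(str(node), k) for node, k in ranking]
    if rule == "sigma":
        values = np.array(list(degrees.values()), dtype=float)
        threshold = values.mean() + 2.0 * values.std()
        hubs = [node for node, k in ranking if k > threshold]
    elif rule == "top_n":
        hubs = [node for node, _ in ranking[:top_n]]
    else:
        raise ValueError(f"unknown hub rule: {rule!r}")
    return HubReport(ranking=ranking, hubs=hubs, rule=rule)


def _exponent(fit: PowerLawFit | float | None) -> float | None:
    if fit is None:
        return None
    return fit.exponent if isinstance(fit, PowerLawFit) else float(fit)


def classify_topology(
    gamma_fit: PowerLawFit | float | None,
    beta_fit: PowerLawFit | float | None,
    alpha_fit: PowerLawFit | float | None,
) -> TopologyClassification:
    """Classify a network from its three power-law order parameters.

    hierarchical: gamma < 2 and beta > 0 and alpha > 0 (low-degree nodes
    attach to controlling hubs); assortative: alpha < 0 (neighborhood
    connectivity increases with degree); scale_free_nonhierarchical:
    gamma >= 2 with |beta| < 0.1 (degree-independent clustering); otherwise
    inconclusive.  Missing fits yield a partial rationale.
    """
    gamma, beta, alpha = map(_exponent, (gamma_fit, beta_fit, alpha_fit))
    rationale = []
    for name, value in (("gamma", gamma), ("beta", beta), ("alpha", alpha)):
        rationale.append(f"{name} missing" if value is None else f"{name} = {value:.3g}")

    if None not in (gamma, beta, alpha) and gamma < 2 and beta > 0 and alpha > 0:
        rationale.append("gamma < 2 with positive beta and alpha: hierarchical organization")
        return TopologyClassification("hierarchical", rationale)
    if alpha is not None and alpha < 0:
        rationale.append("alpha < 0: neighborhood connectivity rises with degree (assortative)")
        return TopologyClassification("assortative", rationale)
    if gamma is not None and beta is not None and gamma >= 2 and abs(beta) < 0.1:
        rationale.append("gamma >= 2 with degree-independent clustering: scale-free, not hierarchical")
        return TopologyClassification("scale_free_nonhierarchical", rationale)
    rationale.append("no classification rule matched")
    return TopologyClassification("inconclusive", rationale)


def analyze_network(graph: nx.Graph) -> dict:
    """Full profile: distributions, power-law fits, hubs and classification."""
    pk = degree_distribution(graph)
    ck = clustering_profile(graph)
    cn = neighborhood_connectivity(graph)
    fits = {}
    for name, profile in (("gamma", pk), ("beta", ck), ("alpha", cn)):
        try:
            fits[name] = power_law_fit({float(k): v for k, v in profile.items()})
        except ValueError:
            fits[name] = None
    classification = classify_topology(fits["gamma"], fits["beta"], fits["alpha"])
    return {
        "degree_distribution": pk,
        "clustering_profile": ck,
        "neighborhood_connectivity": cn,
        "fits": fits,
        "hubs": identify_hubs(graph),
        "classification": classification,
    }
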