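"""Independent brute-force implementations used as oracles in tests.

These deliberately use the most direct O(N^2)/O(N^3) formulations, kept
separate from the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_degree_distribution(edges: list[tuple], nodes: list) -> dict[int, float]:
    degree = {n: 0 for n in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    out: dict[int, float] = {}
    for k in degree.values():
        out[k] = out.get(k, 0) + 1
    return {k: c / len(nodes) for k, c in out.items()}


def brute_clustering_profile(edges: list[tuple], nodes: list) -> dict[int, float]:
    edge_set = {frozenset(e) for e in edges}
    neighbors = {n: set() for n in nodes}
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    per_degree: dict[int, list[float]] = {}
    for n in nodes:
        k = len(neighbors[n])
        if k < 2:
            continue
        nbrs = list(neighbors[n])
        e = 0
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                if frozenset((nbrs[i], nbrs[j])) in edge_set:
                    e += 1
        per_degree.setdefault(k, []).append(2.0 * e / (k * (k - 1)))
    return {k: float(np.mean(v)) for k, v in per_degree.items()}


def brute_neighborhood_connectivity(edges: list[tuple], nodes: list) -> dict[int, float]:
    neighbors = {n: set() for n in nodes}
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    per_degree: dict[int, list[float]] = {}
    for n in nodes:
        k = len(neighbors[n])
        if k == 0:
            continue
        mean_nbr = np.mean([len(neighbors[m]) for m in neighbors[n]])
        per_degree.setdefault(k, []).append(float(mean_nbr))
    return {k: float(np.mean(v)) for k, v in per_degree.items()}


def brute_global_identity(a: str, b: str) -> float:
    """Needleman–Wunsch identity (match 1 / mismatch 0 / gap -1 on matches),
    used only for equal-length no-indel cases where it reduces to column
    comparison."""
    assert len(a) == len(b)
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def brute_anova_f(groups: list[np.ndarray]) -> float:
    """Textbook SSB/SSW computation of the one-way ANOVA F statistic."""
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    return float((ssb / df_b) / (ssw / df_w))


def brute_best_hits(genes_a, genes_b, aligner_stats, min_identity, min_coverage):
    """Exhaustive reciprocal-best-hit computation.

    ``aligner_stats(qseq, sseq)`` returns (identity, query_coverage, score).
    Best passing hit per gene, ties by (-score, -identity, id); pairs kept
    iff mutual.
    """

    def best(queries, subjects):
        out = {}
        for qid, qseq in queries:
            candidates = []
            for sid, sseq in subjects:
                identity, coverage, score = aligner_stats(qseq, sseq)
                if identity >= min_identity and coverage >= min_coverage:
                    candidates.append((-score, -identity, sid))
            out[qid] = min(candidates)[2] if candidates else None
        return out

    ab = best(genes_a, genes_b)
    ba = best(genes_b, genes_a)
    return sorted((qa, qb) for qa, qb in ab.items() if qb is not None and ba.get(qb) == qa)
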