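"""Protein alignment, reciprocal best hits and ortholog clustering.

Orthologous gene families across a genome collection are built from local
pairwise protein alignments (BLOSUM62, affine gaps) filtered at minimum
percent identity and query coverage — 75/75 by default, the thresholds used
for bacterial pangenome screens.  Two clustering strategies are provided:

* **BDBH** — bidirectional best hits against a reference genome; each
  reference gene seeds a cluster joined by its reciprocal best hits in the
  other genomes (at most one member per genome).  Suited to core-genome
  trend curves.
* **COG-triangles** — reciprocal best hits are computed for every genome
  pair; triangles of mutually reciprocal genes across three genomes are
  detected and triangles sharing an edge are merged into clusters.

Identity is reported as identical residue pairs over aligned (non-gap)
columns; coverage as the aligned query span over the query length, matching
BLAST-style conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .simulate import AMINO_ACIDS, Genome, GenomeCollection

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ScoringConfig:
    """Protein scoring: substitution matrix plus affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class AlignmentStats:
    identity: float          # % identical pairs over aligned (non-gap) columns
    query_coverage: float    # % of query length covered by the aligned span
    score: float

    def passes(self, min_identity: float, min_coverage: float) -> bool:
        return self.identity >= min_identity and self.query_coverage >= min_coverage


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g in self.members}


@dataclass
class CogTriangleResult:
    clusters: list[OrthologCluster]
    unmerged_pairs: list[tuple[tuple[str, str], tuple[str, str]]]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "local"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    return seq


def _stats_from_alignment(alignment: Align.Alignment, query_length: int) -> AlignmentStats:
    counts = alignment.counts()
    aligned_columns = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_columns if aligned_columns else 0.0
    # query is the first ("target") sequence handed to the aligner
    q_start, q_end = alignment.coordinates[0, 0], alignment.coordinates[0, -1]
    coverage = 100.0 * float(q_end - q_start) / query_length
    return AlignmentStats(identity=float(identity), query_coverage=coverage, score=float(alignment.score))


def pairwise_align(query: str, subject: str, scoring: ScoringConfig | None = None) -> AlignmentStats:
    """Local alignment of two proteins; returns identity/coverage/score."""
    scoring = scoring or DEFAULT_SCORING
    query = _validate_protein(query, "query")
    subject = _validate_protein(subject, "subject")
    aligner = _aligner(scoring.matrix, scoring.gap_open, scoring.gap_extend)
    alignment = aligner.align(query, subject)[0]
    return _stats_from_alignment(alignment, len(query))


def _genes(genome: Genome | list[tuple[str, str]]) -> list[tuple[str, str]]:
    return genome.genes if isinstance(genome, Genome) else list(genome)


def _best_passing(
    query_idx: int,
    queries: list[tuple[str, str]],
    subjects: list[tuple[str, str]],
    scores: np.ndarray,
    aligner: Align.PairwiseAligner,
    min_identity: float,
    min_coverage: float,
) -> str | None:
    """Best-scoring subject passing the filters; ties by identity then id."""
    qid, qseq = queries[query_idx]
    order = np.argsort(-scores[query_idx], kind="stable")
    j = 0
    while j < len(order):
        score = scores[query_idx, order[j]]
        tied = [int(k) for k in order[j:] if scores[query_idx, k] == score]
        passing: list[tuple[float, str]] = []
        for k in tied:
            sid, sseq = subjects[k]
            stats = _stats_from_alignment(aligner.align(qseq, sseq)[0], len(qseq))
            if stats.passes(min_identity, min_coverage):
                passing.append((stats.identity, sid))
        if passing:
            passing.sort(key=lambda t: (-t[0], t[1]))
            return passing[0][1]
        j += len(tied)
    return None


def best_hits(
    genome_a: Genome | list[tuple[str, str]],
    genome_b: Genome | list[tuple[str, str]],
    min_identity: float = 75.0,
    min_coverage: float = 75.0,
    scoring: ScoringConfig | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two genomes.

    For every gene the best-scoring hit passing the identity/coverage
    filters in the other genome is found; a pair ``(gene_a, gene_b)`` is kept
    only when each is the other's best passing hit.  Score ties break by
    higher identity, then lexicographically smaller gene id.
    """
    scoring = scoring or DEFAULT_SCORING
    genes_a, genes_b = _genes(genome_a), _genes(genome_b)
    if not genes_a or not genes_b:
        logger.warning("best_hits called with an empty genome; returning no pairs")
        return []
    aligner = _aligner(scoring.matrix, scoring.gap_open, scoring.gap_extend)
    seqs_a = [_validate_protein(s, gid) for gid, s in genes_a]
    seqs_b = [_validate_protein(s, gid) for gid, s in genes_b]
    genes_a = [(gid, s) for (gid, _), s in zip(genes_a, seqs_a)]
    genes_b = [(gid, s) for (gid, _), s in zip(genes_b, seqs_b)]

    scores = np.empty((len(genes_a), len(genes_b)))
    for i, (_, sa) in enumerate(genes_a):
        for j, (_, sb) in enumerate(genes_b):
            scores[i, j] = aligner.score(sa, sb)

    best_ab = {
        gid: _best_passing(i, genes_a, genes_b, scores, aligner, min_identity, min_coverage)
        for i, (gid, _) in enumerate(genes_a)
    }
    best_ba = {
        gid: _best_passing(j, genes_b, genes_a, scores.T, aligner, min_identity, min_coverage)
        for j, (gid, _) in enumerate(genes_b)
    }
    pairs = [
        (ga, gb)
        for ga, gb in best_ab.items()
        if gb is not None and best_ba.get(gb) == ga
    ]
    return sorted(pairs)


def bdbh_clusters(
    collection: GenomeCollection,
    reference_genome_id: str | None = None,
    min_identity: float = 75.0,
    min_coverage: float = 75.0,
    scoring: ScoringConfig | None = None,
) -> list[OrthologCluster]:
    """Bidirectional-best-hit clusters seeded on a reference genome.

    Every reference gene seeds one cluster; a gene from another genome joins
    iff it is the reciprocal best hit of the seed.  Clusters therefore hold
    at most one member per genome.  The reference defaults to the first
    genome of the collection.
    """
    if reference_genome_id is None:
        reference_genome_id = collection.genomes[0].genome_id
    try:
        reference = collection.genome(reference_genome_id)
    except KeyError:
        raise ValueError(f"reference genome {reference_genome_id!r} not in collection") from None

    partners: dict[str, list[tuple[str, str]]] = {gid: [] for gid, _ in reference.genes}
    for other in collection.genomes:
        if other.genome_id == reference_genome_id:
            continue
        for ref_gene, other_gene in best_hits(
            reference, other, min_identity, min_coverage, scoring
        ):
            partners[ref_gene].append((other.genome_id, other_gene))

    clusters = []
    for i, (ref_gene, _) in enumerate(sorted(reference.genes)):
        members = [(reference_genome_id, ref_gene)] + sorted(partners[ref_gene])
        clusters.append(OrthologCluster(f"bdbh_{i:05d}", members))
    return clusters


def _rbh_graph(
    collection: GenomeCollection,
    min_identity: float,
    min_coverage: float,
    scoring: ScoringConfig | None,
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """All-pairs reciprocal-best-hit adjacency over (genome_id, gene_id) nodes."""
    adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
    genomes = collection.genomes
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            for ga, gb in best_hits(genomes[i], genomes[j], min_identity, min_coverage, scoring):
                a = (genomes[i].genome_id, ga)
                b = (genomes[j].genome_id, gb)
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
    return adj


def cog_triangle_clusters(
    collection: GenomeCollection,
    min_identity: float = 75.0,
    min_coverage: float = 75.0,
    scoring: ScoringConfig | None = None,
) -> CogTriangleResult:
    """COG-triangles clustering: merge RBH triangles sharing an edge.

    Requires at least three genomes.  Reciprocal best hits are computed for
    all genome pairs; three genes in three genomes that are mutually
    reciprocal form a triangle, and triangles sharing an edge merge into one
    cluster.  Reciprocal pairs not part of any triangle are reported
    separately in :attr:`CogTriangleResult.unmerged_pairs`.
    """
    if len(collection.genomes) < 3:
        raise ValueError("COG-triangles needs >= 3 genomes; use bdbh_clusters for fewer")
    adj = _rbh_graph(collection, min_identity, min_coverage, scoring)

    # union-find over genes, merging via triangles
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    edges = sorted({tuple(sorted((a, b))) for a, nbrs in adj.items() for b in nbrs})
    triangle_edges: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    for a, b in edges:
        common = adj[a] & adj[b]
        for c in common:
            union(a, b)
            union(b, c)
            triangle_edges.update(
                {tuple(sorted((a, b))), tuple(sorted((b, c))), tuple(sorted((a, c)))})

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        groups.setdefault(find(node), []).append(node)
    clusters = [
        OrthologCluster(f"cog_{i:05d}", sorted(members))
        for i, (_, members) in enumerate(sorted(groups.items()))
        if len(members) >= 3
    ]
    unmerged = sorted(e for e in edges if e not in triangle_edges)
    return CogTriangleResult(clusters, unmerged)


def presence_absence(
    clusters: list[OrthologCluster], collection: GenomeCollection
) -> pd.DataFrame:
    """Binary cluster x genome incidence matrix.

    Genes not covered by any cluster become singleton rows, so every gene of
    the collection is represented and row sums equal the number of distinct
    genomes carrying each family.
    """
    genome_ids = collection.genome_ids
    clustered: set[str] = set()
    rows: dict[str, set[str]] = {}
    for cluster in clusters:
        rows[cluster.cluster_id] = cluster.genomes
        clustered |= cluster.gene_ids
    for genome in collection.genomes:
        for gene_id, _ in genome.genes:
            if gene_id not in clustered:
                rows[f"singleton_{gene_id}"] = {genome.genome_id}
    df = pd.DataFrame(0, index=sorted(rows), columns=genome_ids, dtype=int)
    for cluster_id, genomes in rows.items():
        df.loc[cluster_id, sorted(genomes)] = 1
    return df


def partition_labels(
    clusters: list[OrthologCluster], collection: GenomeCollection
) -> tuple[list[str], list[str]]:
    """Per-gene (gene_id, cluster label) lists; unclustered genes get singleton labels.

    Convenience for comparing a clustering against a planted truth map with
    external indices such as the adjusted Rand index.
    """
    assignment: dict[str, str] = {}
    for cluster in clusters:
        for _, gene_id in cluster.members:
            assignment[gene_id] = cluster.cluster_id
    gene_ids, labels = [], []
    for genome in collection.genomes:
        for gene_id, _ in genome.genes:
            gene_ids.append(gene_id)
            labels.append(assignment.get(gene_id, f"singleton_{gene_id}"))
    return gene_ids, labels
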