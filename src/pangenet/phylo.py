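"""Genome distances and trees: ANI, correlation dendrograms, Poisson NJ.

Three complementary views of relatedness are provided:

* **Fragment ANI** — one genome is chopped into consecutive ~1,020 bp
  fragments which are locally aligned (both strands) against the other
  genome; the average nucleotide identity is the mean identity of fragments
  passing minimum-identity and minimum-coverage filters, symmetrised over
  both directions.  An ortholog-based variant averages identity over
  pairwise-aligned single-copy core genes instead.
* **Correlation dendrograms** — hierarchical (average-linkage) clustering on
  ``1 - Pearson r`` between row profiles, e.g. ANI profiles or trait
  presence/absence rows.
* **Poisson-corrected NJ trees** — protein distances ``d = -ln(1 - p)`` for
  the fraction ``p`` of differing sites (gap columns removed), neighbor
  joining, and bootstrap support from column-resampled replicates.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .simulate import reverse_complement

logger = logging.getLogger(__name__)

GAP_CHARACTERS = frozenset("-.")


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

@lru_cache(maxsize=2)
def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def _fragment_identity(fragment: str, target: str) -> tuple[float, float]:
    """Best-strand local alignment of a fragment; (identity %, coverage %)."""
    aligner = _nt_aligner()
    best = None
    for candidate in (fragment, reverse_complement(fragment)):
        score = aligner.score(candidate, target)
        if best is None or score > best[0]:
            best = (score, candidate)
    alignment = aligner.align(best[1], target)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned if aligned else 0.0
    span = alignment.coordinates[0, -1] - alignment.coordinates[0, 0]
    coverage = 100.0 * span / len(fragment)
    return identity, coverage


def ani_fragment(
    genome_a: str,
    genome_b: str,
    fragment_length: int = 1020,
    min_fragment_identity: float = 30.0,
    min_fragment_coverage: float = 70.0,
) -> float | None:
    """One-directional fragment ANI of genome A against genome B.

    Genome A is cut into consecutive fragments (a trailing piece shorter
    than 100 bp is dropped); each fragment is aligned on both strands and
    the identities of fragments passing both filters are averaged.  Returns
    ``None`` when no fragment passes (undefined, not zero).
    """
    if not genome_a or not genome_b:
        raise ValueError("ANI needs two non-empty nucleotide sequences")
    genome_a, genome_b = genome_a.upper(), genome_b.upper()
    identities = []
    for start in range(0, len(genome_a), fragment_length):
        fragment = genome_a[start:start + fragment_length]
        if len(fragment) < 100:
            continue
        identity, coverage = _fragment_identity(fragment, genome_b)
        if identity >= min_fragment_identity and coverage >= min_fragment_coverage:
            identities.append(identity)
    if not identities:
        logger.warning("no fragment passed the ANI filters; ANI undefined")
        return None
    return float(np.mean(identities))


def ani_pair(genome_a: str, genome_b: str, **kwargs) -> float | None:
    """Symmetrised fragment ANI: mean of A->B and B->A."""
    forward = ani_fragment(genome_a, genome_b, **kwargs)
    backward = ani_fragment(genome_b, genome_a, **kwargs)
    values = [v for v in (forward, backward) if v is not None]
    return float(np.mean(values)) if values else None


def ani_matrix(genomes: dict[str, str], **kwargs) -> pd.DataFrame:
    """Symmetric whole-genome fragment-ANI similarity matrix (diagonal 100)."""
    labels = list(genomes)
    out = pd.DataFrame(np.full((len(labels), len(labels)), np.nan), index=labels, columns=labels)
    for label in labels:
        out.loc[label, label] = 100.0
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            value = ani_pair(genomes[a], genomes[b], **kwargs)
            out.loc[a, b] = out.loc[b, a] = np.nan if value is None else value
    return out


def ortholog_ani_matrix(core_genes: dict[str, dict[str, str]]) -> pd.DataFrame:
    """ANI over single-copy core genes: mean pairwise gene identity per genome pair.

    ``core_genes`` maps genome id -> {family id -> nucleotide gene sequence};
    for each genome pair, families present in both are globally aligned and
    the identities averaged.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    labels = list(core_genes)
    out = pd.DataFrame(np.full((len(labels), len(labels)), np.nan), index=labels, columns=labels)
    for label in labels:
        out.loc[label, label] = 100.0
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            shared = sorted(set(core_genes[a]) & set(core_genes[b]))
            if not shared:
                continue
            identities = []
            for family in shared:
                alignment = aligner.align(core_genes[a][family], core_genes[b][family])[0]
                counts = alignment.counts()
                aligned = counts.identities + counts.mismatches
                identities.append(100.0 * counts.identities / aligned if aligned else 0.0)
            out.loc[a, b] = out.loc[b, a] = float(np.mean(identities))
    return out


def ani_to_distance(ani: pd.DataFrame) -> DistanceMatrix:
    """Convert an ANI similarity matrix (%) to a 100-ANI distance matrix."""
    values = 100.0 - ani.to_numpy(dtype=float)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix((values + values.T) / 2.0, ids=list(ani.index))


# ---------------------------------------------------------------------------
# correlation dendrograms
# ---------------------------------------------------------------------------

def correlation_dendrogram(profiles: pd.DataFrame, linkage: str = "average") -> TreeNode:
    """Hierarchical clustering of row profiles on 1 - Pearson r distances.

    Rows are observations (e.g. genomes), columns features (e.g. traits or
    ANI values against each genome).  Identical profiles merge at height 0;
    perfectly anticorrelated profiles are at distance 2.  Constant rows have
    undefined correlation and raise an error naming the row.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    values = profiles.to_numpy(dtype=float)
    constant = profiles.index[values.std(axis=1) == 0].tolist()
    if constant:
        raise ValueError(f"constant rows have undefined Pearson correlation: {constant}")
    corr = np.corrcoef(values)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    link = hierarchy.linkage(condensed, method=linkage)
    newick = _linkage_to_newick(link, list(profiles.index))
    return TreeNode.read([newick])


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return recurse(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Poisson distances and neighbor joining
# ---------------------------------------------------------------------------

def poisson_distance(p: float) -> float:
    """Poisson-corrected distance for a fraction ``p`` of differing sites."""
    if p < 0 or p > 1:
        raise ValueError("p must be in [0, 1]")
    if p >= 1.0:
        return float("inf")
    return float(-np.log1p(-p))


def _strip_gap_columns(sequences: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in sequences])
    keep = ~np.isin(arr, list(GAP_CHARACTERS)).any(axis=0)
    return arr[:, keep]


def poisson_distance_matrix(
    alignment: dict[str, str] | list[tuple[str, str]],
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> tuple[DistanceMatrix, list[DistanceMatrix]]:
    """Pairwise Poisson-corrected distances from an aligned protein matrix.

    Sequences must be equal length; columns containing a gap in any sequence
    are removed first (complete deletion).  ``p`` is the per-pair fraction of
    differing retained sites and ``d = -ln(1 - p)``.  Saturated pairs
    (``p = 1``) get infinite distance.  Bootstrap replicates resample
    retained columns with replacement.
    """
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    labels = [label for label, _ in items]
    sequences = [seq.upper() for _, seq in items]
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    columns = _strip_gap_columns(sequences)
    if columns.shape[1] == 0:
        raise ValueError("no columns left after removing gap-containing columns")

    def matrix_from(cols: np.ndarray) -> DistanceMatrix:
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = float(np.mean(cols[i] != cols[j]))
                d[i, j] = d[j, i] = poisson_distance(p)
        return DistanceMatrix(d, ids=labels)

    main = matrix_from(columns)
    if np.isinf(main.data).any():
        logger.warning("saturated pairs (p = 1) produced infinite Poisson distances")
    replicates = []
    rng = np.random.default_rng(seed)
    for _ in range(bootstrap_reps):
        resampled = columns[:, rng.integers(0, columns.shape[1], size=columns.shape[1])]
        replicates.append(matrix_from(resampled))
    return main, replicates


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial tip bipartitions, each normalised to exclude a reference tip."""
    tips = {t.name for t in tree.tips()}
    reference = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = {t.name for t in node.tips()}
        if len(clade) < 2 or len(tips) - len(clade) < 2:
            continue
        if reference in clade:
            clade = tips - clade
        parts.add(frozenset(clade))
    return parts


def nj_tree(
    matrix: DistanceMatrix, support_matrices: list[DistanceMatrix] | None = None
) -> TreeNode:
    """Saitou–Nei neighbor joining, with optional bootstrap support.

    On an additive distance matrix the reconstructed tree's path lengths
    reproduce the input distances exactly.  If replicate matrices are given,
    each internal node is annotated (as its name) with the percentage of
    replicate NJ trees containing the same tip bipartition.
    """
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if not np.isfinite(matrix.data).all():
        bad = [
            (matrix.ids[i], matrix.ids[j])
            for i in range(len(matrix.ids))
            for j in range(i + 1, len(matrix.ids))
            if not np.isfinite(matrix.data[i, j])
        ]
        raise ValueError(f"non-finite distances for pairs: {bad}")
    tree = nj(matrix)
    if support_matrices:
        # saturated replicates (infinite distances) carry no usable signal
        usable = [r for r in support_matrices if np.isfinite(r.data).all()]
        skipped = len(support_matrices) - len(usable)
        if skipped:
            logger.warning("skipped %d bootstrap replicates with saturated distances", skipped)
        if usable:
            tips = {t.name for t in tree.tips()}
            reference = min(tips)
            counts: dict[frozenset[str], int] = {}
            for replicate in usable:
                for part in _bipartitions(nj(replicate)):
                    counts[part] = counts.get(part, 0) + 1
            for node in tree.non_tips(include_self=False):
                clade = {t.name for t in node.tips()}
                if len(clade) < 2 or len(tips) - len(clade) < 2:
                    continue
                if reference in clade:
                    clade = tips - clade
                pct = 100.0 * counts.get(frozenset(clade), 0) / len(usable)
                node.name = f"{pct:g}"
    return tree


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a tree (for additivity checks)."""
    return tree.tip_tip_distances()
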