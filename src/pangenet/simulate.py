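"""Synthetic data with planted structure for pangenome and network analyses.

Real comparative-genomics studies start from downloaded assemblies and
database-derived interaction networks.  Everything downstream of those inputs
(ortholog clustering, rarefaction, habitat gene-set algebra, distance trees,
network topology statistics) is testable against *planted truth* if the inputs
are simulated with known structure.  This module generates:

* protein genome collections with a universal core, habitat-restricted core
  families and accessory ("cloud") families, at a controlled within-family
  amino-acid identity;
* scale-free (preferential attachment) and hierarchical-modular graphs with
  known topological behaviour;
* block-structured binary trait matrices (e.g. gene presence/absence across
  genomes) with optional flip noise;
* simple nucleotide genomes at controlled divergence, for ANI checks.

All generators are deterministic under their ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# genome collections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PangenomeDesign:
    """Blueprint for a synthetic genome collection.

    Parameters
    ----------
    n_per_habitat
        Habitat label -> number of genomes.  Use :attr:`n_unassigned` for
        genomes without habitat metadata.
    core_size
        Number of universal gene families (present in every genome).
    habitat_core_size
        Number of families private to each habitat and present in every
        genome of that habitat.
    cloud_size
        Number of accessory families, each carried independently by a genome
        with probability ``cloud_presence_prob``.
    within_family_identity
        Target mean *pairwise* percent amino-acid identity among members of
        the same family.
    gene_length_range
        Inclusive range of gene lengths, in residues.
    """

    n_per_habitat: Mapping[str, int] = field(default_factory=dict)
    n_unassigned: int = 0
    core_size: int = 50
    habitat_core_size: int = 0
    cloud_size: int = 0
    cloud_presence_prob: float = 0.2
    within_family_identity: float = 90.0
    gene_length_range: tuple[int, int] = (120, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = list(self.n_per_habitat.values()) + [
            self.n_unassigned, self.core_size, self.habitat_core_size, self.cloud_size]
        if any(c < 0 for c in counts):
            raise ValueError("all design counts must be >= 0")
        if not 0 < self.within_family_identity <= 100:
            raise ValueError("within_family_identity must be in (0, 100]")
        if not 0 <= self.cloud_presence_prob <= 1:
            raise ValueError("cloud_presence_prob must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")

    @property
    def n_genomes(self) -> int:
        return sum(self.n_per_habitat.values()) + self.n_unassigned


@dataclass
class Genome:
    genome_id: str
    habitat: str | None
    genes: list[tuple[str, str]]          # (gene_id, protein sequence)
    nucleotide: str | None = None


@dataclass
class GenomeCollection:
    """A set of genomes plus, for synthetic data, the planted family map."""

    genomes: list[Genome]
    truth: dict[str, str] = field(default_factory=dict)  # gene_id -> family_id

    def __post_init__(self) -> None:
        gids = [g.genome_id for g in self.genomes]
        if len(set(gids)) != len(gids):
            raise ValueError("genome ids must be unique")
        gene_ids = [gid for g in self.genomes for gid, _ in g.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene ids must be unique collection-wide")

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def habitat_map(self) -> dict[str, str | None]:
        return {g.genome_id: g.habitat for g in self.genomes}

    def genome(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def mutate_protein(sequence: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Substitute residues to reach ``target_identity`` percent identity.

    Exactly ``round(L * (1 - target_identity/100))`` positions are chosen
    without replacement and each is replaced by one of the 19 alternative
    residues, drawn uniformly.  No indels are introduced, so the realized
    identity of a global alignment against the parent is analytically exact.
    """
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # (100 - t) / 100 avoids float dust around exact halves, e.g. L=10, t=95
    n_sub = int(round(len(sequence) * (100.0 - target_identity) / 100.0))
    if n_sub == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    out = list(sequence)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(out[pos], "")
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def generate_pangenome_collection(design: PangenomeDesign) -> GenomeCollection:
    """Generate a genome collection with planted family structure.

    Each family has a random ancestor protein; every member is an
    independently mutated copy of the ancestor at *half* the target
    divergence, so the expected pairwise identity between two members equals
    ``design.within_family_identity``.
    """
    if design.n_genomes == 0:
        raise ValueError("design produces zero genomes")
    if design.within_family_identity < 2 * 75 - 100 + 10:  # pairwise id that survives 75% screens
        logger.info(
            "within_family_identity=%.1f may be too low for family members to be "
            "recognizable by 75%%-identity orthology screens", design.within_family_identity)

    rng = np.random.default_rng(design.seed)
    lo, hi = design.gene_length_range
    member_identity = 100.0 - (100.0 - design.within_family_identity) / 2.0

    habitats = sorted(design.n_per_habitat)
    families: list[tuple[str, str, str | None]] = []  # (family_id, ancestor, habitat|None)
    for i in range(design.core_size):
        families.append((f"core_{i:04d}", random_protein(int(rng.integers(lo, hi + 1)), rng), None))
    for hab in habitats:
        for i in range(design.habitat_core_size):
            families.append(
                (f"hab_{hab}_{i:04d}", random_protein(int(rng.integers(lo, hi + 1)), rng), hab))
    cloud_ids = []
    for i in range(design.cloud_size):
        fid = f"cloud_{i:04d}"
        cloud_ids.append(fid)
        families.append((fid, random_protein(int(rng.integers(lo, hi + 1)), rng), "__cloud__"))
    by_id = {fid: (anc, hab) for fid, anc, hab in families}

    genome_specs: list[tuple[str, str | None]] = []
    for hab in habitats:
        for i in range(design.n_per_habitat[hab]):
            genome_specs.append((f"{hab}_{i + 1:02d}", hab))
    for i in range(design.n_unassigned):
        genome_specs.append((f"genome_{i + 1:02d}", None))

    genomes: list[Genome] = []
    truth: dict[str, str] = {}
    for genome_id, habitat in genome_specs:
        carried = [fid for fid, _, fhab in families if fhab is None]
        if habitat is not None:
            carried += [fid for fid, _, fhab in families if fhab == habitat]
        carried += [fid for fid in cloud_ids if rng.random() < design.cloud_presence_prob]
        genes = []
        for k, fid in enumerate(carried):
            gene_id = f"{genome_id}_g{k:04d}"
            ancestor = by_id[fid][0]
            genes.append((gene_id, mutate_protein(ancestor, member_identity, rng)))
            truth[gene_id] = fid
        genomes.append(Genome(genome_id, habitat, genes))

    collection = GenomeCollection(genomes, truth)
    planted = set(truth.values())
    orphans = {fid for fid, _, fhab in families if fhab not in ("__cloud__",)} - planted
    if orphans:
        raise AssertionError(f"planted families without members: {orphans}")
    return collection


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def generate_network(model: str, seed: int = 0, **size_params) -> nx.Graph:
    """Generate a test graph: ``preferential_attachment`` or ``hierarchical_modular``.

    Preferential attachment (Barabási–Albert, ``n_nodes``, ``m_edges``)
    yields a connected scale-free graph.  The hierarchical-modular generator
    (``module_size``, ``levels``) uses deterministic Ravasz-style replication:
    a clique module is copied ``module_size``-fold per level and the
    peripheral nodes of each copy are wired to the original hub, producing
    ``module_size ** levels`` nodes and the C(k) ~ k^-1 signature of
    hierarchical networks.  The seed only permutes node labels there.
    """
    if model == "preferential_attachment":
        n = size_params["n_nodes"]
        m = size_params.get("m_edges", 2)
        if n < 4 or m < 1 or m >= n:
            raise ValueError("preferential attachment requires n_nodes >= 4 and 1 <= m_edges < n_nodes")
        return nx.barabasi_albert_graph(n, m, seed=seed)
    if model == "hierarchical_modular":
        module = size_params["module_size"]
        levels = size_params["levels"]
        if module < 3 or levels < 1:
            raise ValueError("hierarchical_modular requires module_size >= 3 and levels >= 1")
        g, _, _ = _ravasz(module, levels)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(g.number_of_nodes())
        return nx.relabel_nodes(g, {old: int(perm[i]) for i, old in enumerate(sorted(g.nodes))})
    raise ValueError(f"unknown network model: {model!r}")


def _ravasz(module: int, levels: int) -> tuple[nx.Graph, int, list[int]]:
    """Deterministic hierarchical-modular graph; returns (graph, hub, periphery)."""
    g = nx.complete_graph(module)
    hub, periphery = 0, list(range(1, module))
    for _ in range(1, levels):
        combined = nx.Graph(g)
        offset = g.number_of_nodes()
        new_periphery: list[int] = []
        for c in range(1, module):
            shift = offset * c
            mapping = {n: n + shift for n in g.nodes}
            copy = nx.relabel_nodes(g, mapping)
            combined = nx.union(combined, copy)
            for p in periphery:
                combined.add_edge(p + shift, hub)
            new_periphery.extend(p + shift for p in periphery)
        g, periphery = combined, new_periphery
    return g, hub, periphery


# ---------------------------------------------------------------------------
# trait matrices
# ---------------------------------------------------------------------------

def generate_trait_matrix(
    n_genomes: int,
    n_traits: int,
    n_blocks: int = 2,
    flip_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary genome x trait matrix with planted genome blocks.

    Genomes are split into ``n_blocks`` contiguous groups; each block shares
    one random trait profile (profiles are guaranteed non-constant and
    pairwise distinct), then every cell is flipped independently with
    probability ``flip_noise``.
    """
    if n_genomes < n_blocks or n_blocks < 1 or n_traits < 2:
        raise ValueError("need n_genomes >= n_blocks >= 1 and n_traits >= 2")
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    profiles: list[np.ndarray] = []
    while len(profiles) < n_blocks:
        p = rng.integers(0, 2, size=n_traits)
        if p.min() == p.max():
            continue  # constant rows break correlation distances
        if any(np.array_equal(p, q) or np.array_equal(p, 1 - q) for q in profiles):
            continue  # keep block profiles distinguishable and non-collinear
        profiles.append(p)
    bounds = np.linspace(0, n_genomes, n_blocks + 1).astype(int)
    rows = []
    for b in range(n_blocks):
        for _ in range(bounds[b], bounds[b + 1]):
            rows.append(profiles[b].copy())
    matrix = np.array(rows)
    if flip_noise > 0:
        flips = rng.random(matrix.shape) < flip_noise
        matrix = np.where(flips, 1 - matrix, matrix)
    block_of = np.repeat(np.arange(n_blocks), np.diff(bounds))
    # hyphens, not underscores: newick readers treat unquoted "_" as a space
    index = [f"block{block_of[i]}-genome{i:02d}" for i in range(n_genomes)]
    return pd.DataFrame(matrix, index=index, columns=[f"trait_{j:03d}" for j in range(n_traits)])


# ---------------------------------------------------------------------------
# nucleotide genomes (for ANI)
# ---------------------------------------------------------------------------

def random_nucleotide(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def mutate_nucleotide(sequence: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Point-substitute a nucleotide sequence to a target percent identity."""
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(round(len(sequence) * (1.0 - target_identity / 100.0)))
    out = list(sequence)
    for pos in rng.choice(len(sequence), size=n_sub, replace=False):
        out[pos] = NUCLEOTIDES.replace(out[pos], "")[rng.integers(3)]
    return "".join(out)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def clade_genomes(
    n_clades: int = 2,
    genomes_per_clade: int = 2,
    length: int = 8000,
    within_identity: float = 98.0,
    between_identity: float = 85.0,
    seed: int = 0,
) -> dict[str, str]:
    """Nucleotide genomes in divergent clades, for ANI clustering checks."""
    rng = np.random.default_rng(seed)
    root = random_nucleotide(length, rng)
    genomes: dict[str, str] = {}
    for c in range(n_clades):
        ancestor = mutate_nucleotide(root, between_identity, rng) if c else root
        for i in range(genomes_per_clade):
            genomes[f"clade{c}_{i}"] = mutate_nucleotide(ancestor, within_identity, rng)
    return genomes


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_collection(collection: GenomeCollection, outdir: str | Path) -> None:
    """Write one protein FASTA per genome plus genomes.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for genome in collection.genomes:
        fasta = outdir / f"{genome.genome_id}.faa"
        with open(fasta, "w") as fh:
            for gene_id, seq in genome.genes:
                fh.write(f">{gene_id}\n{seq}\n")
        rows.append((genome.genome_id, genome.habitat or "", fasta.name))
    pd.DataFrame(rows, columns=["genome_id", "habitat", "file"]).to_csv(
        outdir / "genomes.tsv", sep="\t", index=False)
    if collection.truth:
        pd.DataFrame(
            sorted(collection.truth.items()), columns=["gene_id", "family_id"]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_collection(directory: str | Path) -> GenomeCollection:
    """Read a collection written by :func:`write_collection`."""
    from Bio import SeqIO

    directory = Path(directory)
    table = pd.read_csv(directory / "genomes.tsv", sep="\t", keep_default_na=False)
    genomes = []
    for _, row in table.iterrows():
        genes = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(directory / row["file"], "fasta")]
        genomes.append(Genome(row["genome_id"], row["habitat"] or None, genes))
    truth_path = directory / "truth.tsv"
    truth = {}
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        truth = dict(zip(tdf["gene_id"], tdf["family_id"]))
    return GenomeCollection(genomes, truth)


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(map(str, e))) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")
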