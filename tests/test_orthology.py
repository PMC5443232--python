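import numpy as np
import pytest

from oracles import brute_best_hits
from pangenet.orthology import (
    OrthologCluster,
    bdbh_clusters,
    best_hits,
    cog_triangle_clusters,
    pairwise_align,
    partition_labels,
    presence_absence,
)
from pangenet.simulate import (
    Genome,
    GenomeCollection,
    PangenomeDesign,
    generate_pangenome_collection,
    mutate_protein,
    random_protein,
)


class TestPairwiseAlign:
    def test_identical_sequences(self, rng):
        seq = random_protein(20, rng)
        stats = pairwise_align(seq, seq)
        assert stats.identity == 100.0
        assert stats.query_coverage == 100.0

    def test_five_of_twenty_substitutions_give_75_percent(self, rng):
        # substitution-only mutant: the alignment has no gaps, so identity is
        # exactly matched columns over 20
        seq = random_protein(20, rng)
        mutant = mutate_protein(seq, 75.0, 3)
        assert sum(a != b for a, b in zip(seq, mutant)) == 5
        stats = pairwise_align(seq, mutant)
        if stats.query_coverage == 100.0:  # full-length local alignment
            assert stats.identity == pytest.approx(75.0)

    def test_unrelated_sequences_have_low_identity(self):
        rng = np.random.default_rng(99)
        low = 0
        for _ in range(25):
            a, b = random_protein(200, rng), random_protein(200, rng)
            stats = pairwise_align(a, b)
            # local alignments of random proteins find short high-identity
            # islands; full-coverage identity cannot stay high
            if stats.identity < 40 or stats.query_coverage < 75:
                low += 1
        assert low == 25

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "MKV")
        with pytest.raises(ValueError):
            pairwise_align("MKV", "MK1")


def _two_genomes_from_families(n_families, identity, seed, length=(80, 140)):
    rng = np.random.default_rng(seed)
    ancestors = [random_protein(int(rng.integers(*length)), rng) for _ in range(n_families)]
    genes_a = [(f"a{i:03d}", mutate_protein(anc, identity, rng)) for i, anc in enumerate(ancestors)]
    genes_b = [(f"b{i:03d}", mutate_protein(anc, identity, rng)) for i, anc in enumerate(ancestors)]
    return genes_a, genes_b


class TestBestHits:
    def test_identical_copies_all_paired(self, rng):
        genes = [(f"g{i}", random_protein(60, rng)) for i in range(4)]
        copies = [(f"h{i}", seq) for i, (_, seq) in enumerate(genes)]
        pairs = best_hits(genes, copies)
        assert pairs == [(f"g{i}", f"h{i}") for i in range(4)]

    def test_reciprocity(self):
        genes_a, genes_b = _two_genomes_from_families(6, 95, seed=8)
        ab = best_hits(genes_a, genes_b)
        ba = best_hits(genes_b, genes_a)
        assert sorted((y, x) for x, y in ab) == ba

    def test_families_below_threshold_yield_no_pairs(self):
        genes_a, genes_b = _two_genomes_from_families(5, 50, seed=9, length=(150, 200))
        assert best_hits(genes_a, genes_b, min_identity=75, min_coverage=75) == []

    def test_threshold_monotonicity(self):
        genes_a, genes_b = _two_genomes_from_families(8, 90, seed=10)
        n_pairs = [
            len(best_hits(genes_a, genes_b, min_identity=t)) for t in (50, 75, 90, 97)
        ]
        assert n_pairs == sorted(n_pairs, reverse=True)

    def test_empty_genome_returns_empty(self, rng):
        assert best_hits([], [("x", random_protein(30, rng))]) == []

    def test_matches_brute_force_oracle(self):
        genes_a, genes_b = _two_genomes_from_families(6, 85, seed=21)

        def stats(q, s):
            st = pairwise_align(q, s)
            return st.identity, st.query_coverage, st.score

        expected = brute_best_hits(genes_a, genes_b, stats, 75, 75)
        assert best_hits(genes_a, genes_b) == expected


class TestClustering:
    def test_bdbh_on_identical_families(self, rng):
        seqs = [random_protein(70, rng) for _ in range(3)]
        genomes = [
            Genome(f"G{j}", None, [(f"G{j}f{i}", s) for i, s in enumerate(seqs)])
            for j in range(3)
        ]
        clusters = bdbh_clusters(GenomeCollection(genomes))
        assert len(clusters) == 3
        assert all(len(c.members) == 3 for c in clusters)
        assert all(len(c.genomes) == 3 for c in clusters)

    def test_bdbh_missing_family_gives_smaller_cluster(self, rng):
        seqs = [random_protein(70, rng) for _ in range(2)]
        genomes = [
            Genome("GA", None, [("a0", seqs[0]), ("a1", seqs[1])]),
            Genome("GB", None, [("b0", seqs[0])]),
        ]
        clusters = bdbh_clusters(GenomeCollection(genomes))
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_bdbh_unknown_reference_errors(self, small_collection):
        with pytest.raises(ValueError):
            bdbh_clusters(small_collection, reference_genome_id="nope")

    def test_bdbh_recovers_planted_partition(self, small_collection):
        from sklearn.metrics import adjusted_rand_score

        clusters = bdbh_clusters(small_collection)
        gene_ids, labels = partition_labels(clusters, small_collection)
        truth = [small_collection.truth[g] for g in gene_ids]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_cog_triangles_require_three_genomes(self, rng):
        seq = random_protein(50, rng)
        genomes = [Genome("A", None, [("a", seq)]), Genome("B", None, [("b", seq)])]
        with pytest.raises(ValueError, match="bdbh"):
            cog_triangle_clusters(GenomeCollection(genomes))

    def test_cog_triangles_one_shared_family(self, rng):
        seq = random_protein(80, rng)
        genomes = [Genome(f"G{j}", None, [(f"g{j}", seq)]) for j in range(3)]
        result = cog_triangle_clusters(GenomeCollection(genomes))
        assert len(result.clusters) == 1
        assert len(result.clusters[0].members) == 3
        assert result.unmerged_pairs == []

    def test_cog_triangles_recover_planted_families(self, small_collection):
        from sklearn.metrics import adjusted_rand_score

        result = cog_triangle_clusters(small_collection)
        assert len(result.clusters) == 12  # planted family count, no cloud
        gene_ids, labels = partition_labels(result.clusters, small_collection)
        truth = [small_collection.truth[g] for g in gene_ids]
        assert adjusted_rand_score(truth, labels) == 1.0


class TestPresenceAbsence:
    def test_toy_incidence(self):
        genomes = [
            Genome("A", None, [("a1", "MKLV" * 10), ("a2", "MPWC" * 10)]),
            Genome("B", None, [("b1", "MKLV" * 10), ("b3", "MHRD" * 10)]),
            Genome("C", None, [("c1", "MKLV" * 10), ("c4", "MYGN" * 10)]),
        ]
        collection = GenomeCollection(genomes)
        clusters = [OrthologCluster("f1", [("A", "a1"), ("B", "b1"), ("C", "c1")])]
        matrix = presence_absence(clusters, collection)
        assert matrix.loc["f1"].tolist() == [1, 1, 1]
        singles = matrix.drop(index="f1")
        assert (singles.sum(axis=1) == 1).all()
        # one cluster row plus three unclustered singleton genes
        assert matrix.shape == (4, 3)

    def test_empty_cluster_list_gives_singletons_only(self, small_collection):
        matrix = presence_absence([], small_collection)
        assert (matrix.sum(axis=1) == 1).all()
        n_genes = sum(len(g.genes) for g in small_collection.genomes)
        assert matrix.shape[0] == n_genes

    def test_row_sums_equal_cluster_genome_counts(self, small_collection):
        clusters = bdbh_clusters(small_collection)
        matrix = presence_absence(clusters, small_collection)
        for cluster in clusters:
            assert matrix.loc[cluster.cluster_id].sum() == len(cluster.genomes)
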