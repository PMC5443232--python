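import numpy as np
import pytest
from skbio import DistanceMatrix

from pangenet.phylo import (
    ani_matrix,
    ani_pair,
    ani_to_distance,
    correlation_dendrogram,
    nj_tree,
    ortholog_ani_matrix,
    poisson_distance,
    poisson_distance_matrix,
    tree_path_distances,
)
from pangenet.simulate import (
    clade_genomes,
    generate_trait_matrix,
    mutate_nucleotide,
    random_nucleotide,
    reverse_complement,
)


class TestPoissonDistance:
    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0.0), (0.5, 0.6931471805599453), (0.1, 0.10536051565782628)]
    )
    def test_closed_form(self, p, expected):
        assert poisson_distance(p) == pytest.approx(expected, rel=1e-12)

    def test_saturation_is_infinite(self):
        assert poisson_distance(1.0) == float("inf")

    def test_monotone_and_bounded_below_by_p(self):
        ps = np.linspace(0.0, 0.95, 50)
        ds = [poisson_distance(p) for p in ps]
        assert all(b >= a for a, b in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, ps))

    def test_matrix_with_gap_columns_removed(self):
        alignment = {
            "s1": "ACDEFGHIKL",
            "s2": "ACDEFGHIKV",   # 1/10 differs
            "s3": "ACDEF-HIKL",   # gap column dropped for everyone
        }
        matrix, _ = poisson_distance_matrix(alignment)
        # after complete deletion 9 columns remain; s1 vs s2 differ at 1
        assert matrix["s1", "s2"] == pytest.approx(-np.log(1 - 1 / 9))
        assert matrix["s1", "s3"] == 0.0

    def test_bootstrap_reproducible_and_counted(self):
        alignment = {"a": "AAAAAAAAAA", "b": "AAAAACCCCC", "c": "CCCCCCCCCC"}
        _, reps1 = poisson_distance_matrix(alignment, bootstrap_reps=7, seed=3)
        _, reps2 = poisson_distance_matrix(alignment, bootstrap_reps=7, seed=3)
        assert len(reps1) == 7
        assert all((r1.data == r2.data).all() for r1, r2 in zip(reps1, reps2))

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance_matrix({"a": "AAA", "b": "AA"})


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_reproduced_exactly(self):
        dm = DistanceMatrix(
            np.array([[0, 17, 21, 27], [17, 0, 12, 18], [21, 12, 0, 14], [27, 18, 14, 0]], float),
            ids=list("abcd"))
        tree = nj_tree(dm)
        paths = tree_path_distances(tree).filter(list("abcd"))
        assert np.allclose(paths.data, dm.data)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float), ids=list("xyz"))
        tree = nj_tree(dm)
        paths = tree_path_distances(tree).filter(list("xyz"))
        assert np.allclose(paths.data, dm.data)

    def test_two_clade_bootstrap_support_is_full_on_clean_data(self):
        # 2-clade alignment whose only informative signal is the clade split
        # (within-clade differences are autapomorphies): the bootstrap
        # cannot support any competing bipartition
        alignment = {
            "a1": "G" * 20 + "AAAAAA" + "CAAA",
            "a2": "G" * 20 + "AAAAAA" + "ACAA",
            "b1": "G" * 20 + "TTTTTT" + "AACA",
            "b2": "G" * 20 + "TTTTTT" + "AAAC",
        }
        matrix, reps = poisson_distance_matrix(alignment, bootstrap_reps=50, seed=9)
        tree = nj_tree(matrix, support_matrices=reps)
        supports = [float(n.name) for n in tree.non_tips() if n.name is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_infinite_distances_rejected_with_pairs(self):
        data = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(DistanceMatrix(data, ids=list("pqr")))

    def test_newick_roundtrip_preserves_leaves(self):
        dm = DistanceMatrix(
            np.array([[0, 2, 5, 6], [2, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]], float),
            ids=["t1", "t2", "t3", "t4"])
        tree = nj_tree(dm)
        newick = str(tree)
        from skbio import TreeNode
        back = TreeNode.read([newick])
        assert {t.name for t in back.tips()} == {"t1", "t2", "t3", "t4"}


class TestCorrelationDendrogram:
    def test_identical_profiles_merge_at_zero(self):
        import pandas as pd

        profiles = pd.DataFrame(
            [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], index=["r1", "r2", "r3"])
        tree = correlation_dendrogram(profiles)
        lca = tree.lca(["r1", "r2"])
        assert tree_path_distances(tree)["r1", "r2"] == pytest.approx(0.0, abs=1e-12)
        # anticorrelated r3 merges at height 2 (= 1 - (-1)); the tip-to-tip
        # path traverses both sides of the dendrogram, so it is twice that
        assert tree_path_distances(tree)["r1", "r3"] == pytest.approx(4.0, abs=1e-12)
        assert lca is not tree  # r1, r2 cluster below the root

    def test_constant_row_is_named_in_error(self):
        import pandas as pd

        profiles = pd.DataFrame([[1, 1, 1], [1, 0, 1]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_dendrogram(profiles)

    def test_two_block_fixture_splits_at_root(self):
        traits = generate_trait_matrix(6, 12, n_blocks=2, flip_noise=0.0, seed=6)
        tree = correlation_dendrogram(traits)
        left, right = tree.children
        sides = [{t.name for t in child.tips()} | ({child.name} if child.is_tip() else set())
                 for child in (left, right)]
        sides = [{n for n in side if n} for side in sides]
        blocks = [
            {i for i in traits.index if i.startswith("block0")},
            {i for i in traits.index if i.startswith("block1")},
        ]
        assert sides in ([blocks[0], blocks[1]], [blocks[1], blocks[0]])


class TestANI:
    def test_self_ani_is_100(self):
        rng = np.random.default_rng(2)
        genome = random_nucleotide(3000, rng)
        assert ani_pair(genome, genome) == pytest.approx(100.0)

    def test_reverse_complement_strand_handling(self):
        rng = np.random.default_rng(3)
        genome = random_nucleotide(3000, rng)
        assert ani_pair(genome, reverse_complement(genome)) == pytest.approx(100.0)

    def test_five_percent_mutant(self):
        rng = np.random.default_rng(4)
        genome = random_nucleotide(4000, rng)
        mutant = mutate_nucleotide(genome, 95.0, rng)
        assert ani_pair(genome, mutant) == pytest.approx(95.0, abs=0.5)

    def test_matrix_symmetric_with_clade_structure(self):
        genomes = clade_genomes(
            n_clades=2, genomes_per_clade=2, length=3000,
            within_identity=99.0, between_identity=88.0, seed=5)
        matrix = ani_matrix(genomes)
        arr = matrix.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 100.0)
        within = [matrix.loc["clade0_0", "clade0_1"], matrix.loc["clade1_0", "clade1_1"]]
        between = [
            matrix.loc[a, b]
            for a in ("clade0_0", "clade0_1")
            for b in ("clade1_0", "clade1_1")
        ]
        assert min(within) > max(between)
        dm = ani_to_distance(matrix)
        assert dm["clade0_0", "clade0_0"] == 0.0

    def test_ortholog_core_mode(self):
        rng = np.random.default_rng(6)
        core = {f"f{i}": random_nucleotide(900, rng) for i in range(3)}
        genomes = {
            "g1": {f: mutate_nucleotide(s, 99.0, rng) for f, s in core.items()},
            "g2": {f: mutate_nucleotide(s, 99.0, rng) for f, s in core.items()},
            "g3": {f: mutate_nucleotide(s, 90.0, rng) for f, s in core.items()},
        }
        matrix = ortholog_ani_matrix(genomes)
        assert matrix.loc["g1", "g2"] > matrix.loc["g1", "g3"]
        assert matrix.loc["g1", "g2"] == pytest.approx(98.0, abs=1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ani_pair("", "ACGT")
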