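import math
from functools import lru_cache

import numpy as np
import pytest

from conftest import random_seq
from estforge.phylo import (DistanceMatrix, PairwiseAlignment, SaturationError,
                            UndefinedDistanceError, jukes_cantor, nw_align,
                            p_distance, pairwise_distance, robinson_foulds,
                            upgma)

GAP = 8.0
MATCH, MISMATCH = 5.0, -4.0


def oracle_nw_score(a: str, b: str) -> float:
    """Exhaustive best global alignment score (recursive over all moves)."""

    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + go(i + 1, j + 1))
        if i < len(a):
            best = max(best, -GAP + go(i + 1, j))
        if j < len(b):
            best = max(best, -GAP + go(i, j + 1))
        return best

    return go(0, 0)


class TestNeedlemanWunsch:
    def test_perfect_match_score(self):
        aln = nw_align("ACGT", "ACGT", gap=GAP)
        assert aln.score == 20.0
        assert aln.aligned_a == aln.aligned_b == "ACGT"

    def test_length_mismatch_forces_gaps(self):
        # best alignment of AAA vs A: one match + two gap bases
        assert nw_align("AAA", "A", gap=GAP).score == 5.0 - 16.0

    def test_symmetry(self, rng):
        a, b = random_seq(rng, 30), random_seq(rng, 25)
        assert nw_align(a, b, gap=GAP).score == nw_align(b, a, gap=GAP).score

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(1, 9)))
        b = random_seq(rng, int(rng.integers(1, 9)))
        assert nw_align(a, b, gap=GAP).score == pytest.approx(oracle_nw_score(a, b))

    def test_band_matches_full_when_wide_enough(self, rng):
        a, b = random_seq(rng, 60), random_seq(rng, 58)
        full = nw_align(a, b, gap=GAP)
        banded = nw_align(a, b, gap=GAP, band=30)
        assert banded.score == full.score


class TestPDistance:
    def test_identical(self):
        p, n = p_distance(PairwiseAlignment("ACGTACGTAC", "ACGTACGTAC", 0))
        assert p == 0.0 and n == 10

    def test_one_in_ten(self):
        p, n = p_distance(PairwiseAlignment("ACGTACGTAC", "ACGTACGTAT", 0))
        assert p == 0.1 and n == 10

    def test_ns_and_gaps_excluded_from_denominator(self):
        p, n = p_distance(PairwiseAlignment("ACGTN-CG", "ACGTAACG", 0))
        assert n == 6 and p == 0.0

    def test_no_columns_raises(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance(PairwiseAlignment("NNN", "NNN", 0))


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_at_p01(self):
        assert jukes_cantor(0.1) == pytest.approx(0.1073256, abs=1e-6)

    def test_strictly_increasing_and_superlinear(self):
        grid = np.linspace(0.0, 0.74, 200)
        d = np.array([jukes_cantor(p) for p in grid])
        assert (np.diff(d) > 0).all()
        assert (d[1:] > grid[1:]).all()  # d >= p with equality only at 0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)
        # approaching the pole the distance blows up
        assert jukes_cantor(0.7499) > 2.5


class TestPairwiseDistance:
    def test_matches_string_pipeline(self, rng):
        a = random_seq(rng, 200)
        b_list = list(a)
        for i in range(0, 200, 10):
            b_list[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b_list[i]]
        b = "".join(b_list)
        pd = pairwise_distance(a, b)
        aln = nw_align(a, b)
        p, cols = p_distance(aln)
        assert pd.p == pytest.approx(p) and pd.aligned_columns == cols
        assert pd.d == pytest.approx(jukes_cantor(p))
        assert pd.p == pytest.approx(0.1)


def random_ultrametric(rng, n_taxa):
    """Random ultrametric tree -> (labels, matrix, newick)."""
    labels = [f"L{i}" for i in range(n_taxa)]
    from estforge.phylo import PhyloTree, TreeNode

    nodes = [TreeNode(0.0, lab) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = TreeNode(height, None, [nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = PhyloTree(nodes[0])
    dm = tree.distance_matrix(labels)
    return tree, dm


class TestUpgma:
    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]),
                            np.ones((2, 2), int))
        assert upgma(dm).to_newick() == "(A:1,B:1);"

    def test_three_taxa_hand_example(self):
        m = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], m, np.ones((3, 3), int))
        assert upgma(dm).to_newick() == "((A:1,B:1):1,C:2);"

    @pytest.mark.parametrize("seed", range(10))
    def test_ultrametric_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        true_tree, dm = random_ultrametric(rng, int(rng.integers(3, 9)))
        est = upgma(dm)
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert est.path_distance(a, b) == pytest.approx(
                    dm.matrix[i, j], abs=1e-9)
        assert robinson_foulds(est.to_newick(), true_tree.to_newick()) == 0

    def test_label_order_invariance(self):
        m = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
        dm1 = DistanceMatrix(["A", "B", "C"], m, np.ones((3, 3), int))
        perm = [2, 0, 1]
        m2 = m[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(["C", "A", "B"], m2, np.ones((3, 3), int))
        t1, t2 = upgma(dm1), upgma(dm2)
        assert robinson_foulds(t1.to_newick(), t2.to_newick()) == 0
        assert t1.path_distance("A", "C") == t2.path_distance("A", "C")

    def test_missing_cells_refused(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = DistanceMatrix(["A", "B"], m, np.ones((2, 2), int))
        with pytest.raises(ValueError):
            upgma(dm)

    def test_single_label_refused(self):
        dm = DistanceMatrix(["A"], np.zeros((1, 1)), np.ones((1, 1), int))
        with pytest.raises(ValueError):
            upgma(dm)


class TestNewickRoundTrip:
    def test_dendropy_reparses_identically(self):
        import dendropy

        m = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], m, np.ones((3, 3), int))
        nwk = upgma(dm).to_newick()
        t = dendropy.Tree.get(data=nwk, schema="newick")
        # leaf depths from the root reproduce the ultrametric heights
        for leaf in t.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(2.0)


class TestScoreMatrix:
    def test_mean_scores_symmetric_and_scaled(self, rng):
        from estforge.phylo import CommonEst, average_score_matrix

        a = random_seq(rng, 100)
        common = [CommonEst("e1", {"x": a, "y": a}),
                  CommonEst("e2", {"x": a, "y": a})]
        sm = average_score_matrix(common, ["x", "y"], scale=1e-4)
        # identical sequences: NW score = 5 per column
        assert sm.matrix[0, 1] == pytest.approx(5.0 * 100 * 1e-4)
        assert sm.matrix[0, 1] == sm.matrix[1, 0]
        assert sm.n_common[0, 1] == 2
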