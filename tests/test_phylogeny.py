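import numpy as np
import pytest
from Bio.Align import substitution_matrices

from _oracles import best_alignment_score, nj_bipartitions, random_additive_matrix
from cdpkfam import phylogeny as ph
from cdpkfam.errors import InputError
from cdpkfam.seqio import ProteinRecord, write_newick


def _tree_bipartitions(tree):
    leaves = sorted(t.name for t in tree.tips())
    anchor, universe = leaves[0], frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(universe - side if anchor in side else side)
    return out


def _branch_lengths(tree):
    return sorted(
        round(n.length, 9) for n in tree.traverse(include_self=False)
    )


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = ph.global_align("ACDEF", "ACDEF")
        stats = ph.pairwise_stats(aln, 5)
        assert (stats.coverage, stats.identity) == (1.0, 1.0)
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_mismatch_five_mers(self):
        aln = ph.global_align("ACDEF", "ACDFF")
        stats = ph.pairwise_stats(aln, 5)
        assert stats.identity == pytest.approx(4 / 5)

    @pytest.mark.parametrize("a,b", [("ACDEF", "ACDFF"), ("MKLV", "MKV"),
                                     ("WWF", "FWW"), ("ACACA", "CACAC")])
    def test_score_matches_exhaustive_enumeration(self, a, b):
        mat = substitution_matrices.load("BLOSUM62")
        aln = ph.global_align(a, b)
        expected = best_alignment_score(
            a, b, lambda x, y: float(mat[x, y]), 10.0, 0.5
        )
        assert aln.score == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            ph.global_align("A", "")

    def test_non_residue_characters_rejected(self):
        with pytest.raises(InputError):
            ph.global_align("ACD1", "ACD")


class TestPairwiseStats:
    def test_identical_hundred_mers(self):
        s = "ACDEFGHIKL" * 10
        stats = ph.pairwise_identity(s, s)
        assert (stats.coverage, stats.identity) == (1.0, 1.0)

    def test_prefix_coverage(self):
        long = "ACDEFGHIKLMNPQRSTVWY" * 5
        stats = ph.pairwise_identity(long, long[:80])
        assert stats.coverage == pytest.approx(0.8)
        assert stats.identity == pytest.approx(1.0)

    def test_fully_gapped_alignment_flagged(self):
        aln = ph.PairwiseAlignment("AA--", "--CC", 0.0)
        stats = ph.pairwise_stats(aln, 2)
        assert stats.identity_undefined
        assert stats.identity == 0.0


class TestDistanceMatrix:
    def test_identical_records_give_zero_offdiagonals(self):
        recs = [ProteinRecord(i, "ACDEFGHIKL" * 3) for i in "ABC"]
        dm = ph.p_distance_matrix(recs)
        assert np.allclose(dm.d, 0)

    def test_symmetry_random_records(self):
        rng = np.random.default_rng(4)
        recs = [
            ProteinRecord(f"r{i}",
                          "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                             size=40)))
            for i in range(5)
        ]
        dm = ph.p_distance_matrix(recs)
        assert np.allclose(dm.d, dm.d.T)
        assert (dm.d >= 0).all()

    def test_duplicate_labels_rejected(self):
        recs = [ProteinRecord("x", "ACDEF")] * 3
        with pytest.raises(InputError):
            ph.p_distance_matrix(recs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InputError):
            ph.DistanceMatrix(list("ABC"),
                              np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = ph.DistanceMatrix(list("ABC"),
                               np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                                        float))
        tree = ph.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 3.0, "C": 5.0}
        # path lengths reproduce the input distances exactly
        assert lengths["A"] + lengths["B"] == 4
        assert lengths["A"] + lengths["C"] == 6
        assert lengths["B"] + lengths["C"] == 8

    def test_additive_four_leaf_recovery(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = ph.neighbor_joining(ph.DistanceMatrix(list("ABCD"), d))
        assert _tree_bipartitions(tree) == {frozenset("CD")}
        assert _branch_lengths(tree) == [1.0, 1.0, 2.0, 3.0, 4.0]

    @pytest.mark.parametrize("n", [4, 5])
    def test_additive_matrices_recover_generating_topology(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(20):
            labels, d, true_splits = random_additive_matrix(rng, n)
            tree = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
            assert _tree_bipartitions(tree) == true_splits

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            labels = [chr(ord("A") + i) for i in range(n)]
            m = rng.uniform(0.05, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = ph.neighbor_joining(ph.DistanceMatrix(labels, m))
            oracle_splits, oracle_lengths = nj_bipartitions(labels, m)
            assert _tree_bipartitions(tree) == oracle_splits
            assert _branch_lengths(tree) == pytest.approx(oracle_lengths)

    def test_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = ph.DistanceMatrix(list("ABCD"), d)
        assert write_newick(ph.neighbor_joining(dm)) == write_newick(
            ph.neighbor_joining(dm)
        )


class TestBootstrap:
    LABELS = ["A1", "A2", "A3", "B1", "B2", "B3"]
    ROWS = ["AAAAAAAAAACCCCCCCCCC"] * 3 + ["GGGGGGGGGGTTTTTTTTTT"] * 3

    def test_separating_bipartition_gets_full_support(self):
        tree = ph.bootstrap_supports(self.LABELS, self.ROWS,
                                     n_replicates=50, seed=1)
        supports = {
            frozenset(t.name for t in node.tips()): int(node.name)
            for node in tree.non_tips(include_self=False)
            if node.name is not None
        }
        split = frozenset(self.LABELS[:3])
        complement = frozenset(self.LABELS[3:])
        assert any(
            supports.get(s) == 100 for s in (split, complement)
        )

    def test_single_replicate_supports_are_binary(self):
        tree = ph.bootstrap_supports(self.LABELS, self.ROWS,
                                     n_replicates=1, seed=0)
        vals = {int(n.name) for n in tree.non_tips(include_self=False)
                if n.name is not None}
        assert vals <= {0, 100}

    def test_same_seed_reproduces_supports(self):
        t1 = ph.bootstrap_supports(self.LABELS, self.ROWS, 25, seed=9)
        t2 = ph.bootstrap_supports(self.LABELS, self.ROWS, 25, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_invariant_to_row_order(self):
        order = [3, 0, 4, 1, 5, 2]
        t1 = ph.bootstrap_supports(self.LABELS, self.ROWS, 25, seed=9)
        t2 = ph.bootstrap_supports([self.LABELS[i] for i in order],
                                   [self.ROWS[i] for i in order], 25, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_ragged_rows_rejected(self):
        with pytest.raises(InputError):
            ph.bootstrap_supports(["a", "b", "c"], ["AAA", "AA", "AAA"], 5, 0)


class TestGroupAssignment:
    def _tree(self):
        from cdpkfam.seqio import parse_newick
        return parse_newick(
            "(((q1:1,r1a:1):1,r1b:1):2,((r2a:1,r2b:1):1,q2:4):2);"
        )

    def test_query_in_pure_reference_clade(self):
        refs = {"r1a": "I", "r1b": "I", "r2a": "II", "r2b": "II"}
        groups = ph.assign_groups(self._tree(), refs)
        assert groups["q1"] == "I"
        assert groups["q2"] == "II"

    def test_mixed_smallest_clade_is_unassigned(self):
        tree = self._tree()
        refs = {"r1a": "I", "r2a": "I", "r1b": "II", "r2b": "II"}
        groups = ph.assign_groups(tree, refs)
        # q1's smallest reference-containing side holds only r1a -> pure I
        assert groups["q1"] == "I"
        # q2's smallest such side holds r2a (I) and r2b (II) -> mixed
        assert groups["q2"] == "unassigned"

    def test_reference_group_too_small_errors(self):
        with pytest.raises(InputError):
            ph.assign_groups(self._tree(), {"r1a": "I", "r2a": "II",
                                            "r2b": "II"})

    def test_planted_groups_recovered_at_stated_separation(self):
        """Parameter recovery: four groups planted at ~80% within-group
        and ~40% between-group identity are assigned back correctly."""
        from cdpkfam import synthetic_data as sd

        config = sd.GeneratorConfig(
            seed=11,
            groups=tuple(sd.GroupSpec(n, 5) for n in ("I", "II", "III", "IV")),
            duplications=(),
            within_group_identity=0.80,
            between_group_identity=0.40,
            n_background_genes=0,
        )
        genome = sd.generate_family_genome(config)
        records = [r for r in genome.proteins]
        tree = ph.neighbor_joining(ph.p_distance_matrix(records))
        labels = genome.truth.group_labels
        refs = {}
        for grp in ("I", "II", "III", "IV"):
            for member in [m for m, g in labels.items() if g == grp][:2]:
                refs[member] = grp
        assigned = ph.assign_groups(tree, refs)
        correct = sum(assigned[q] == labels[q] for q in assigned)
        assert correct / len(assigned) >= 0.95
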