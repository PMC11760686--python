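"""Alignment, distance, and neighbor-joining correctness against oracles."""
import io as stdio
import math

import numpy as np
import pytest
from skbio.tree import TreeNode

from markergeo import phylo
from markergeo import simulate as sim

AA = phylo.AA20


def random_protein(rng, length):
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def pairwise_nw_oracle(a, b, gap_open=-10.0, gap_extend=-1.0):
    """Independent affine-gap global DP on two sequences (BLOSUM62)."""
    from Bio.Align import substitution_matrices

    S = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend, X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def alignment_score(row_a, row_b, gap_open=-10.0, gap_extend=-1.0):
    """Score of a given pairwise alignment under the MSA scoring scheme."""
    from Bio.Align import substitution_matrices

    S = substitution_matrices.load("BLOSUM62")
    score = 0.0
    in_gap = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += S[ca, cb]
            in_gap = False
    return score


class TestProgressiveMSA:
    def test_single_sequence_is_its_own_alignment(self):
        aln = phylo.progressive_msa({"a": "MKV"})
        assert aln.rows == {"a": "MKV"} and aln.n_cols == 3

    def test_identical_sequences_align_gap_free(self):
        s = random_protein(np.random.default_rng(0), 40)
        aln = phylo.progressive_msa({"a": s, "b": s, "c": s})
        assert all(row == s for row in aln.rows.values())

    def test_internal_insertion_produces_one_gap_block(self):
        rng = np.random.default_rng(1)
        a = random_protein(rng, 30)
        b = a[:14] + "WWW" + a[14:]
        aln = phylo.progressive_msa({"a": a, "b": b})
        assert aln.ungapped("a") == a and aln.ungapped("b") == b
        assert aln.rows["b"].count("-") == 0
        gaps = aln.rows["a"]
        assert gaps.count("-") == 3
        start = gaps.index("-")
        assert gaps[start : start + 3] == "---"

    def test_pairwise_alignment_is_optimal_against_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(15, 40)))
            b = list(a)
            # a few substitutions and one deletion
            for pos in rng.choice(len(a), size=3, replace=False):
                b[pos] = AA[int(rng.integers(20))]
            cut = int(rng.integers(2, len(a) - 4))
            b = "".join(b[:cut] + b[cut + 2 :])
            aln = phylo.progressive_msa({"a": a, "b": b})
            got = alignment_score(aln.rows["a"], aln.rows["b"])
            assert got == pytest.approx(pairwise_nw_oracle(a, b))

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": random_protein(rng, int(rng.integers(20, 50))) for i in range(8)}
        aln = phylo.progressive_msa(seqs)
        for sid, s in seqs.items():
            assert aln.ungapped(sid) == s

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            phylo.progressive_msa({"a": "MKV*"})


class TestTrimAndDrop:
    def test_gap_free_alignment_unchanged(self):
        aln = phylo.Alignment({"a": "MKV", "b": "MRV"})
        assert phylo.trim_gappy_columns(aln).rows == aln.rows
        assert phylo.drop_gappy_sequences(aln).rows == aln.rows

    def test_column_gapped_in_three_of_four_rows_dropped(self):
        aln = phylo.Alignment({"a": "M-K", "b": "M-K", "c": "M-K", "d": "MWK"})
        out = phylo.trim_gappy_columns(aln, 0.5)
        assert out.rows == {"a": "MK", "b": "MK", "c": "MK", "d": "MK"}

    def test_trimmed_columns_respect_threshold_property(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n_rows, n_cols = int(rng.integers(2, 8)), int(rng.integers(4, 30))
            rows = {}
            for r in range(n_rows):
                rows[f"s{r}"] = "".join(
                    "-" if rng.random() < 0.4 else AA[int(rng.integers(20))]
                    for _ in range(n_cols)
                )
            aln = phylo.Alignment(rows)
            try:
                out = phylo.trim_gappy_columns(aln, 0.5)
            except ValueError:
                continue
            vals = list(out.rows.values())
            for c in range(out.n_cols):
                gap_frac = sum(1 for v in vals if v[c] == "-") / n_rows
                assert gap_frac <= 0.5

    def test_sequence_gap_threshold_is_strict(self):
        # 51% gaps removed, exactly 50% retained
        aln = phylo.Alignment({
            "gappy": "-" * 51 + "M" * 49,
            "edge": "-" * 50 + "M" * 50,
            "full": "M" * 100,
        })
        out = phylo.drop_gappy_sequences(aln, 0.5)
        assert set(out.rows) == {"edge", "full"}

    def test_all_dropped_raises(self):
        aln = phylo.Alignment({"a": "-M-M", "b": "M-M-"})
        with pytest.raises(ValueError):
            phylo.trim_gappy_columns(aln, 0.1)
        with pytest.raises(ValueError):
            phylo.drop_gappy_sequences(phylo.Alignment({"a": "---M"}), 0.1)


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        aln = phylo.Alignment({"a": "MKVLAW", "b": "MKVLAW"})
        dm = phylo.protein_distance_matrix(aln)
        assert dm["a", "b"] == 0.0

    def test_corrected_distance_formula(self):
        # p = 0.1 -> d = -(19/20) ln(1 - (20/19) * 0.1)
        a = "A" * 10
        b = "C" + "A" * 9
        dm = phylo.protein_distance_matrix(phylo.Alignment({"a": a, "b": b}))
        expected = -(19 / 20) * math.log(1 - (20 / 19) * 0.1)
        assert dm["a", "b"] == pytest.approx(expected)
        assert expected == pytest.approx(0.1057, abs=1e-4)

    def test_saturated_pairs_capped(self):
        aln = phylo.Alignment({"a": "ACDEF" * 4, "b": "KLMNP" * 4})
        dm = phylo.protein_distance_matrix(aln)
        assert dm["a", "b"] == phylo.MAX_DISTANCE

    def test_disjoint_gap_patterns_raise_naming_pair(self):
        aln = phylo.Alignment({"a": "MK--", "b": "--MK"})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            phylo.protein_distance_matrix(aln)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        rows = {f"s{i}": random_protein(rng, 30) for i in range(5)}
        dm = phylo.protein_distance_matrix(phylo.Alignment(rows))
        d = np.asarray(dm.data)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)


def random_additive_tree(rng, n):
    """Random binary tree with branch lengths; returns (tree, ids)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = phylo.nj_tree(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):2,C:4,D:5) gives this additive matrix
        d = np.array(
            [[0, 5, 8, 9], [5, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = phylo.nj_tree(d, ["A", "B", "C", "D"])
        truth = TreeNode.read(stdio.StringIO("((A:2,B:3):2,C:4,D:5);"))
        assert tree.compare_rfd(truth) == 0.0
        got = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1 :]:
                assert got[a, b] == pytest.approx(d["ABCD".index(a), "ABCD".index(b)])

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            truth = random_additive_tree(rng, n)
            dm = truth.tip_tip_distances()
            tree = phylo.nj_tree(np.asarray(dm.data), list(dm.ids))
            assert tree.compare_rfd(truth) == 0.0
            got = tree.tip_tip_distances()
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1 :]:
                    assert got[a, b] == pytest.approx(dm[a, b])

    def test_agrees_with_skbio_reference_nj(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix

        rng = np.random.default_rng(7)
        truth = random_additive_tree(rng, 8)
        dm_data = truth.tip_tip_distances()
        dm = DistanceMatrix(np.asarray(dm_data.data), list(dm_data.ids))
        ours = phylo.nj_tree(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_two_taxa_single_branch(self):
        tree = phylo.nj_tree(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["A"] + tips["B"] == pytest.approx(4.0)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(d, ["A", "B"])

    def test_negative_estimates_clamped_to_zero(self):
        d = np.array(
            [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.6, 0.6], [0.6, 0.6, 0, 0.01], [0.6, 0.6, 0.01, 0]],
        )
        tree = phylo.nj_tree(d, list("ABCD"))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0

    def test_topology_recovered_from_simulated_proteins(self):
        """End-to-end: sequences evolved on a known 16-taxon tree with every
        branch at 0.1 substitutions/site rebuild that topology exactly.
        Deeper trees saturate the 131-column protein distances."""
        truth_tree = sim.simulate_tree(16, seed=42)
        for node in truth_tree.traverse(include_self=False):
            node.length = 0.1
        nt = sim.evolve_marker(truth_tree, length=393, seed=42)
        from Bio.Seq import Seq

        aa = {name: str(Seq(s).translate()) for name, s in nt.items()}
        aln = phylo.progressive_msa(aa)
        aln = phylo.trim_gappy_columns(aln)
        dm = phylo.protein_distance_matrix(aln)
        tree = phylo.nj_tree(dm)
        assert tree.compare_rfd(truth_tree) == 0.0


class TestNewickIO:
    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(8)
        truth = random_additive_tree(rng, 7)
        p = tmp_path / "t.nwk"
        phylo.write_newick(truth, p)
        back = phylo.read_newick(p)
        assert back.compare_rfd(truth) == 0.0
        a, b = truth.tip_tip_distances(), back.tip_tip_distances()
        for i, x in enumerate(a.ids):
            for y in a.ids[i + 1 :]:
                assert b[x, y] == pytest.approx(a[x, y], abs=1e-6)

    def test_two_leaf_string(self, tmp_path):
        p = tmp_path / "two.nwk"
        p.write_text("(A:1,B:2);\n")
        tree = phylo.read_newick(p)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"A": 1.0, "B": 2.0}

    def test_truncated_file_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:2")
        with pytest.raises(ValueError, match="parse"):
            phylo.read_newick(p)


class TestLongBranchFlags:
    def test_outlier_tip_flagged(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,B:0.1):0.05,(C:0.1,D:2.0):0.05);\n")
        tree = phylo.read_newick(p)
        assert phylo.flag_long_branches(tree, factor=5.0) == ["D"]
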