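import math
from itertools import combinations

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from markerkit.barcode_phylo import (
    classify_sites,
    count_si_sv,
    distance_matrix,
    nj_tree,
    pairwise_distance,
    tree_report,
)
from markerkit.errors import SaturationError, ValidationError
from markerkit.io import SequenceSet


def brute_force_column_class(col):
    """Independent per-column classifier used as oracle."""
    if "-" in col or any(c not in "ACGT" for c in col):
        return "excluded"
    counts = {c: col.count(c) for c in set(col)}
    if len(counts) == 1:
        return "conserved"
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return "informative"
    return "singleton"


def random_alignment(rng, n_seqs=4, length=60, gap_rate=0.05):
    seqs = []
    for _ in range(n_seqs):
        s = rng.choice(list("ACGT"), size=length)
        gaps = rng.random(length) < gap_rate
        seqs.append("".join("-" if g else c for c, g in zip(s, gaps)))
    return SequenceSet(ids=[f"s{i}" for i in range(n_seqs)], seqs=seqs, aligned=True)


class TestSiteClassification:
    def test_identical_sequences_all_conserved(self):
        aln = SequenceSet(ids=["a", "b", "c", "d"], seqs=["ACGT"] * 4, aligned=True)
        s = classify_sites(aln)
        assert s.n_conserved == 4 and s.n_variable == 0

    def test_singleton_and_informative_columns(self):
        aln = SequenceSet(
            ids=list("abcd"), seqs=["AA", "AA", "AG", "GG"], aligned=True
        )
        s = classify_sites(aln)
        # col1 A,A,A,G singleton; col2 A,A,G,G informative
        assert s.n_singleton == 1 and s.n_parsimony_informative == 1

    def test_gap_columns_counted_and_excluded(self):
        aln = SequenceSet(
            ids=list("ab"), seqs=["A-GT", "ACGT"], aligned=True
        )
        s = classify_sites(aln)
        assert s.n_indel_sites == 1
        assert s.n_conserved + s.n_variable + s.n_excluded == s.n_sites

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            aln = random_alignment(rng)
            s = classify_sites(aln)
            cols = ["".join(c) for c in zip(*aln.seqs)]
            classes = [brute_force_column_class(c) for c in cols]
            assert s.n_conserved == classes.count("conserved")
            assert s.n_parsimony_informative == classes.count("informative")
            assert s.n_singleton == classes.count("singleton")
            assert s.n_excluded == classes.count("excluded")
            assert s.n_conserved + s.n_variable + s.n_excluded == s.n_sites

    def test_unaligned_input_rejected(self):
        sset = SequenceSet(ids=["a", "b"], seqs=["ACGT", "ACGTT"], aligned=False)
        with pytest.raises(ValidationError):
            classify_sites(sset)


class TestSiSv:
    def test_single_transition_gives_undefined_ratio(self):
        aln = SequenceSet(ids=["a", "b"], seqs=["AAAA", "GAAA"], aligned=True)
        si, sv, r = count_si_sv(aln)
        assert (si, sv, r) == (1, 0, None)

    def test_constructed_ratio_of_four(self):
        # 4 transition columns (A->G) and 1 transversion column (A->C)
        aln = SequenceSet(ids=["a", "b"], seqs=["AAAAA", "GGGGC"], aligned=True)
        si, sv, r = count_si_sv(aln)
        assert (si, sv) == (4, 1)
        assert r == pytest.approx(4.0)

    def test_identical_pair_undefined(self):
        aln = SequenceSet(ids=["a", "b"], seqs=["ACGT", "ACGT"], aligned=True)
        assert count_si_sv(aln) == (0, 0, None)

    def test_complete_vs_pairwise_deletion(self):
        aln = SequenceSet(
            ids=list("abc"), seqs=["AC-A", "GCCA", "GCAA"], aligned=True
        )
        si_c, sv_c, _ = count_si_sv(aln, gaps="complete")
        si_p, sv_p, _ = count_si_sv(aln, gaps="pairwise")
        assert (si_c, sv_c) == (2, 0)  # column 3 dropped for everyone
        assert (si_p, sv_p) == (2, 1)  # b/c pair still compares column 3


class TestDistances:
    def test_identical_sequences_are_at_zero(self):
        s = "ACGTACGTGC"
        for model in ("p", "k2p", "t3p"):
            assert pairwise_distance(s, s, model) == pytest.approx(0.0)

    def test_k2p_closed_form(self):
        # P = 1/8, Q = 0 -> d = -1/2 ln(3/4)
        s1, s2 = "A" * 8, "G" + "A" * 7
        assert pairwise_distance(s1, s2, "k2p") == pytest.approx(
            -0.5 * math.log(0.75)
        )

    def test_t3p_reduces_to_k2p_at_half_gc(self):
        s1 = "ACGT" * 6
        # two compensating transitions (A->G, G->A) keep mean GC at 0.5
        s2 = "GCGT" + "ACAT" + "ACGT" * 4
        k2p = pairwise_distance(s1, s2, "k2p")
        t3p = pairwise_distance(s1, s2, "t3p")
        assert t3p == pytest.approx(k2p, rel=1e-12)

    def test_k2p_dominates_p_distance(self, rng):
        for _ in range(10):
            s1 = "".join(rng.choice(list("ACGT"), size=100))
            s2 = "".join(
                c if rng.random() > 0.15 else rng.choice(list("ACGT"))
                for c in s1
            )
            try:
                k2p = pairwise_distance(s1, s2, "k2p")
            except SaturationError:
                continue
            assert k2p >= pairwise_distance(s1, s2, "p") - 1e-12

    def test_saturation_raises(self):
        s1 = "ACACACACAC"
        s2 = "CACACACACA"  # all transversions: Q = 1
        with pytest.raises(SaturationError):
            pairwise_distance(s1, s2, "k2p")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_distance("ACGT", "ACG", "k2p")


def random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns (tree, dm)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 0.5))) for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.05, 0.5))
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes)
    dm = root.tip_tip_distances()
    return root, dm


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = nj_tree(DistanceMatrix([[0, 0.07], [0.07, 0]], ids=["a", "b"]))
        assert tree.tip_tip_distances()["a", "b"] == pytest.approx(0.07)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(d, ids=list("abc")))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrix_reproduced_exactly(self, rng, n):
        _, dm = random_additive_tree(rng, n)
        tree = nj_tree(dm)
        out = tree.tip_tip_distances()
        for a, b in combinations(dm.ids, 2):
            assert out[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_agrees_with_skbio_reference_on_additive_input(self, rng):
        _, dm = random_additive_tree(rng, 6)
        ours = nj_tree(dm).tip_tip_distances()
        ref = skbio_nj(dm).tip_tip_distances()
        for a, b in combinations(dm.ids, 2):
            assert ours[a, b] == pytest.approx(ref[a, b], abs=1e-6)

    def test_negative_branches_clamped_with_warning(self):
        d = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.65, 0.1],
                [0.6, 0.65, 0.0, 0.6],
                [0.6, 0.1, 0.6, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="negative NJ branch"):
            tree = nj_tree(DistanceMatrix(d, ids=list("abcd")))
        assert all((t.length or 0) >= 0 for t in tree.postorder())

    def test_non_symmetric_rejected(self):
        with pytest.raises(Exception):
            nj_tree(np.array([[0, 1.0, 2.0], [0.5, 0, 1.0], [2.0, 1.0, 0]]))


class TestTreeReport:
    def test_path_sum_on_constructed_tree(self):
        tree = TreeNode.read(["((A:0.01,H:0.025):0.0,(M:0.02,J:0.03):0.01);"])
        rep = tree_report(tree)
        assert rep.distance("A", "H") == pytest.approx(0.035)
        assert rep.same_clade("A", "H") and not rep.same_clade("A", "J")

    def test_distances_match_cophenetic_oracle(self, rng):
        tree, dm = random_additive_tree(rng, 6)
        rep = tree_report(tree)
        for a, b in combinations(dm.ids, 2):
            assert rep.distance(a, b) == pytest.approx(dm[a, b])

    def test_matrix_wide_distances_and_nj_from_alignment(self):
        aln = SequenceSet(
            ids=list("abcd"),
            seqs=["ACGTACGTAC", "ACGTACGTGC", "ACGAACTTGC", "TCGAACTTGA"],
            aligned=True,
        )
        dm = distance_matrix(aln, model="k2p")
        assert dm["a", "a"] == 0
        tree = nj_tree(dm)
        assert {t.name for t in tree.tips()} == set("abcd")
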