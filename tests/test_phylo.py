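"""Concatenation summary statistics, JC69 distances, neighbor-joining and
bootstrap supports."""

import math

import numpy as np
import pytest

from plastome_compare import reference_tables as rt
from plastome_compare.divergence import RegionAlignment, percent_variability
from plastome_compare.phylo import (TreeNode, alignment_summary, bipartitions,
                                    bootstrap, jc69_distance, jc69_from_p,
                                    neighbor_joining, nj_tree,
                                    parsimony_informative_sites,
                                    robinson_foulds, write_phylip)


def _aln(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows))]
    return RegionAlignment(name="x", taxa=taxa, rows=rows)


class TestSummary:
    def test_pi_classifier_on_toy_columns(self):
        # columns: (A,A,T,T) PI, (A,T,C,G) var not PI, (A,A,A,A) const,
        # (A,A,A,T) var not PI, (C,C,C,C) const, (G,G,C,C) PI
        rows = ["AAAACG", "ATAACG", "TCAACC", "TGATCC"]
        aln = _aln(rows)
        s = alignment_summary(aln)
        assert s.variable_positions == 4
        assert s.parsimony_informative == 2

    def test_pi_ignores_gap_state(self):
        assert parsimony_informative_sites(["A", "A", "-", "-"]) == 0
        assert parsimony_informative_sites(["A", "A", "T", "T"]) == 1

    def test_all_identical_alignment(self):
        s = alignment_summary(_aln(["ACGT" * 3] * 4))
        assert (s.variable_positions, s.parsimony_informative,
                s.percent_variability) == (0, 0, 0.0)

    def test_printed_totals_imply_S_535_and_P_051(self):
        t = rt.CONCAT_TOTALS
        S = t["variable_positions"] - t["indel_length"]
        assert S == 535
        assert percent_variability(S, t["indel_events"], t["aligned_length"]) == 0.51

    def test_pi_le_variable_le_length(self, concat_alignment):
        s = alignment_summary(concat_alignment)
        assert s.parsimony_informative <= s.variable_positions <= s.aligned_length


class TestJC69:
    def test_identical_rows_give_zero(self):
        d = jc69_distance(_aln(["ACGTACGT", "ACGTACGT"]))
        assert d[0, 1] == 0.0

    def test_closed_form_at_p_01(self):
        assert jc69_from_p(0.1) == pytest.approx(0.1073, abs=5e-5)

    def test_pairwise_deletion(self):
        # pair columns without gaps: 4; one mismatch -> p = 0.25
        d = jc69_distance(_aln(["ACGTA", "-CGTT"]))
        assert d[0, 1] == pytest.approx(jc69_from_p(0.25))

    def test_saturated_pair_raises_with_names(self):
        with pytest.raises(ValueError, match="ta|tb"):
            jc69_distance(_aln(["AAAA", "TTTT"], taxa=["ta", "tb"]))


def random_additive_tree(rng, n):
    """Random binary topology with uniform branch lengths; returns the
    TreeNode, its leaf-to-leaf path-length matrix, and the labels."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[(nodes[i], float(rng.uniform(0.05, 1.0))),
                                    (nodes[j], float(rng.uniform(0.05, 1.0)))])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=[(x, float(rng.uniform(0.05, 1.0))) for x in nodes])

    # undirected adjacency, then path lengths by DFS from every leaf
    adj = {}

    def connect(node):
        for c, bl in node.children:
            adj.setdefault(id(node), []).append((id(c), bl))
            adj.setdefault(id(c), []).append((id(node), bl))
            connect(c)

    leaf_of = {}

    def collect(node):
        if not node.children:
            leaf_of[id(node)] = node.name
        for c, _ in node.children:
            collect(c)

    connect(root)
    collect(root)
    labels = sorted(leaf_of.values())
    idx = {l: k for k, l in enumerate(labels)}
    leaf_ids = {v: k for k, v in leaf_of.items()}
    D = np.zeros((n, n))
    for lab in labels:
        start = leaf_ids[lab]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, bl in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + bl
                    stack.append(v)
        for nid, other in leaf_of.items():
            D[idx[lab], idx[other]] = dist[nid]
    return root, D, labels


class TestNJ:
    def test_three_taxa_exact_branch_lengths(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        bl = {c.name: l for c, l in tree.children}
        assert bl == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_matrix(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1)
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float)
        tree = neighbor_joining(d, list("ABCD"))
        assert bipartitions(tree) == {frozenset("AB")}
        lengths = sorted(round(l, 6) for _, l in _edges(tree))
        assert lengths == [1.0] * 5  # four pendant edges + one internal

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            true, D, labels = random_additive_tree(rng, n)
            est = neighbor_joining(D, labels)
            assert robinson_foulds(est, true) == 0

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        true, D, labels = random_additive_tree(rng, 8)
        noisy = D + rng.uniform(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        mine = neighbor_joining(noisy, labels)
        sk = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
        sk_bips = set()
        n_leaves = len(labels)
        for node in sk.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n_leaves - 1:
                other = frozenset(labels) - below
                sk_bips.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        assert bipartitions(mine) == sk_bips

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(d, list("abc"))


def _edges(node):
    for c, l in node.children:
        yield c, l
        yield from _edges(c)


class TestBootstrap:
    def test_consistent_alignment_gives_full_support(self):
        rows = ["TTTTTTTTACGTACGT", "TTTTTTTTACGTACGT",
                "AAAAAAAAACGTACGT", "AAAAAAAAACGTACGT"]
        aln = _aln(rows)
        tree = bootstrap(aln, n_reps=50, seed=3)
        supports = [c.support for c, _ in _edges(tree) if c.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproduces_supports(self, concat_alignment):
        a = bootstrap(concat_alignment, n_reps=20, seed=11)
        b = bootstrap(concat_alignment, n_reps=20, seed=11)
        assert a.newick() == b.newick()

    def test_nonpositive_reps_rejected(self, concat_alignment):
        with pytest.raises(ValueError):
            bootstrap(concat_alignment, n_reps=0, seed=1)

    def test_supports_within_0_100(self, concat_alignment):
        tree = bootstrap(concat_alignment, n_reps=20, seed=5)
        for c, _ in _edges(tree):
            if c.support is not None:
                assert 0.0 <= c.support <= 100.0


class TestExport:
    def test_phylip_roundtrip_shape(self, tmp_path):
        aln = _aln(["ACGT", "ACGA", "AC-T"], taxa=["a b", "c", "d"])
        p = tmp_path / "x.phy"
        write_phylip(aln, p)
        lines = p.read_text().splitlines()
        assert lines[0].split() == ["3", "4"]
        assert lines[1].startswith("a_b")

    def test_newick_parses_with_dendropy(self, concat_alignment):
        import dendropy
        tree = nj_tree(concat_alignment)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == len(concat_alignment.taxa)
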