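"""Distances, neighbor joining, bootstrap, Newick."""

import math

import dendropy
import numpy as np
import pytest

from sydeslim.conservation import MultipleAlignment
from sydeslim.phylogeny import (DistanceMatrix, MAX_DISTANCE, TreeNode,
                                bipartitions, bootstrap_supports,
                                distance_matrix, neighbor_joining,
                                protein_distance, write_newick)


def test_protein_distance_identical_zero():
    assert protein_distance("ACDEF", "ACDEF") == 0.0


def test_protein_distance_half_mismatch():
    # p = 0.5 -> d = -ln(1 - 0.5 - 0.2*0.25) = -ln(0.45)
    assert protein_distance("AAAA", "AAGG") == pytest.approx(-math.log(0.45))


def test_protein_distance_ignores_gap_columns():
    assert protein_distance("A-CD", "AG-D") == 0.0  # only columns 1 and 4 shared


def test_protein_distance_monotone_in_p():
    ds = []
    for k in range(0, 9):
        a = "A" * 10
        b = "G" * k + "A" * (10 - k)
        ds.append(protein_distance(a, b))
    assert ds == sorted(ds)


def test_protein_distance_saturation_capped():
    with pytest.warns(UserWarning, match="saturated"):
        assert protein_distance("AAAA", "GGGG") == MAX_DISTANCE


def test_protein_distance_no_shared_columns_errors():
    with pytest.raises(ValueError, match="no shared"):
        protein_distance("A--", "-GG")


def test_nj_three_taxa_closed_form():
    labels = ("A", "B", "C")
    m = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(labels, m))
    lengths = {child.name: bl for child, bl in tree.children}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


def additive_matrix():
    # ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
    labels = ("A", "B", "C", "D")
    d = {
        ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
        ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
    }
    m = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                m[i, j] = d[tuple(sorted((x, y)))]
    return DistanceMatrix(labels, m)


def test_nj_recovers_additive_four_taxon_split():
    tree = neighbor_joining(additive_matrix())
    assert frozenset({"A", "B"}) in bipartitions(tree) or \
        frozenset({"C", "D"}) in bipartitions(tree)


def test_nj_additive_branch_lengths_sum():
    # total tree length of the generating tree is 2+3+1+4+5 = 15
    tree = neighbor_joining(additive_matrix())

    def total(node):
        return sum(bl + total(ch) for ch, bl in node.children)

    assert total(tree) == pytest.approx(15.0, abs=1e-9)


def test_nj_two_taxa_degenerate():
    tree = neighbor_joining(
        DistanceMatrix(("A", "B"), np.array([[0.0, 4.0], [4.0, 0.0]]))
    )
    assert sorted(ch.name for ch, _ in tree.children) == ["A", "B"]
    assert sum(bl for _, bl in tree.children) == pytest.approx(4.0)


def synthetic_two_clade_msa(n_cols=300, seed=1):
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = letters[rng.integers(0, 20, n_cols)]
    cladeB = base.copy()
    # high divergence between clades
    flip = rng.random(n_cols) < 0.5
    cladeB[flip] = letters[rng.integers(0, 20, flip.sum())]

    def mutate(seq, rate):
        seq = seq.copy()
        hit = rng.random(n_cols) < rate
        seq[hit] = letters[rng.integers(0, 20, hit.sum())]
        return seq

    rows = {
        "a1": "".join(mutate(base, 0.02)),
        "a2": "".join(mutate(base, 0.02)),
        "b1": "".join(mutate(cladeB, 0.02)),
        "b2": "".join(mutate(cladeB, 0.02)),
    }
    return MultipleAlignment(rows)


def test_bootstrap_recovers_clean_clades():
    msa = synthetic_two_clade_msa()
    tree = bootstrap_supports(msa, n_replicates=100, seed=5)
    parts = bipartitions(tree)
    key = frozenset({"b1", "b2"})
    assert key in parts or frozenset({"a1", "a2"}) in parts

    def supports(node):
        out = []
        if node.support is not None:
            out.append(node.support)
        for ch, _ in node.children:
            out.extend(supports(ch))
        return out

    assert all(s >= 95 for s in supports(tree))


def test_bootstrap_deterministic_for_fixed_seed():
    msa = synthetic_two_clade_msa()
    t1 = bootstrap_supports(msa, n_replicates=30, seed=9)
    t2 = bootstrap_supports(msa, n_replicates=30, seed=9)
    assert write_newick(t1) == write_newick(t2)


def test_bootstrap_invariant_to_taxa_order():
    msa = synthetic_two_clade_msa()
    reordered = MultipleAlignment(dict(reversed(list(msa.rows.items()))))
    def support_map(tree):
        out = {}
        all_leaves = frozenset(tree.leaves())
        def visit(node):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c, _ in node.children))
            if node.support is not None:
                other = all_leaves - below
                out[below if min(below) > min(other) else other] = node.support
            return below
        for c, _ in tree.children:
            visit(c)
        return out
    s1 = support_map(bootstrap_supports(msa, n_replicates=30, seed=9))
    s2 = support_map(bootstrap_supports(reordered, n_replicates=30, seed=9))
    assert s1 == s2


def test_identical_sequences_handled_without_crash():
    msa = MultipleAlignment({f"s{i}": "ACDEFACDEF" for i in range(4)})
    tree = bootstrap_supports(msa, n_replicates=10, seed=1)
    assert sorted(tree.leaves()) == ["s0", "s1", "s2", "s3"]


def test_newick_two_leaf_form():
    tree = TreeNode(children=[(TreeNode(name="A"), 1.5), (TreeNode(name="B"), 2.5)])
    assert write_newick(tree) == "(A:1.5,B:2.5);"


def test_newick_quotes_metacharacter_labels():
    tree = TreeNode(children=[(TreeNode(name="D. rerio"), 1.0),
                              (TreeNode(name="B"), 2.0)])
    text = write_newick(tree)
    assert "'D. rerio'" in text
    parsed = dendropy.Tree.get(data=text, schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"D. rerio", "B"}


def test_newick_round_trip_topology_and_lengths():
    msa = synthetic_two_clade_msa(seed=3)
    tree = neighbor_joining(distance_matrix(msa))
    text = write_newick(tree)
    parsed = dendropy.Tree.get(data=text, schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(msa.rows)
    parsed_len = sum(e.length for e in parsed.edges() if e.length)

    def total(node):
        return sum(bl + total(ch) for ch, bl in node.children)

    assert parsed_len == pytest.approx(total(tree), rel=1e-4)
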