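"""Distances, NJ/UPGMA, Fitch parsimony, MP search, bootstrap, RF."""
import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from plastidmark import phylogeny as ph
from plastidmark import synthetic_data as sd
from plastidmark.core_io import MultipleAlignment

from conftest import additive_matrix, random_binary_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


# ------------------------------------------------------------------ distances

def test_identical_rows_have_zero_distance():
    aln = MultipleAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
    assert ph.pairwise_distances(aln, model="p").matrix[0, 1] == 0.0


def test_jc69_closed_form():
    # 30 mismatches over 100 sites: p = 0.3
    row_a = "A" * 100
    row_b = "C" * 30 + "A" * 70
    aln = MultipleAlignment(["a", "b"], [row_a, row_b])
    d = ph.pairwise_distances(aln, model="JC69").matrix[0, 1]
    assert d == pytest.approx(-0.75 * math.log(1 - 0.4), abs=1e-9)
    assert d == pytest.approx(0.383119, abs=1e-6)


def test_complete_deletion_excludes_gap_columns_for_all_pairs():
    aln = MultipleAlignment(
        ["a", "b", "c"],
        ["ACGT", "AC-T", "ACTT"],
    )
    dm = ph.pairwise_distances(aln, model="p", gap_mode="complete")
    # the gap column in b (where a and c also differ) is excluded everywhere
    assert dm.get("a", "c") == 0.0
    dm2 = ph.pairwise_distances(aln, model="p", gap_mode="pairwise")
    assert dm2.get("a", "c") == pytest.approx(1 / 4)


def test_jc69_saturation_names_the_pair():
    aln = MultipleAlignment(["near", "far"], ["A" * 20, "C" * 20])
    with pytest.raises(ph.SaturationError, match="near.*far"):
        ph.pairwise_distances(aln, model="JC69")


def test_jc69_monotone_in_p():
    last = -1.0
    for mismatches in range(0, 70, 5):
        aln = MultipleAlignment(
            ["a", "b"], ["A" * 100, "C" * mismatches + "A" * (100 - mismatches)]
        )
        d = ph.pairwise_distances(aln, model="JC69").matrix[0, 1]
        assert d > last
        last = d


# ------------------------------------------------------------------- NJ/UPGMA

def test_nj_three_taxon_branch_lengths():
    dm = ph.DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    )
    tree = ph.build_nj(dm)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


@pytest.mark.parametrize("seed", range(20))
def test_nj_recovers_topology_from_additive_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 11))
    labels = [f"t{i}" for i in range(n)]
    true = random_binary_tree(labels, rng)
    taxa, m = additive_matrix(true)
    nj = ph.build_nj(ph.DistanceMatrix(taxa, m))
    assert ph.rf_distance(nj, true) == 0


def test_upgma_recovers_ultrametric_tree_with_heights():
    # ((A,B):1,(C,D):1) with heights 1 and 3: ultrametric distances
    taxa = ["A", "B", "C", "D"]
    m = np.array(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
    )
    tree = ph.build_upgma(ph.DistanceMatrix(taxa, m))
    assert ph.rf_distance(tree, _tree("((A:1,B:1):2,(C:1,D:1):2);")) == 0
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths[leaf.taxon.label] = d
    assert all(d == pytest.approx(3.0) for d in depths.values())


def test_nj_rejects_too_few_taxa():
    dm = ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
    with pytest.raises(ValueError):
        ph.build_nj(dm)


# ---------------------------------------------------------------------- Fitch

def test_fitch_trivial_columns():
    tree = _tree("((A1,A2),(B1,B2));")
    invariant = MultipleAlignment(["A1", "A2", "B1", "B2"], ["A", "A", "A", "A"])
    assert ph.fitch_score(tree, invariant) == 0
    split = MultipleAlignment(["A1", "A2", "B1", "B2"], ["A", "A", "T", "T"])
    assert ph.fitch_score(tree, split) == 1


def test_fitch_gaps_are_free():
    tree = _tree("((A1,A2),(B1,B2));")
    aln = MultipleAlignment(["A1", "A2", "B1", "B2"], ["A", "-", "T", "N"])
    assert ph.fitch_score(tree, aln) == 1


def _sankoff_min_steps(tuple_tree, column):
    """Independent oracle: per-column Sankoff DP over unit costs."""
    INF = 10**6

    def rec(node):
        if isinstance(node, str):
            base = column[node]
            if base not in "ACGT":
                return [0, 0, 0, 0]
            return [0 if b == base else INF for b in "ACGT"]
        lc, rc = rec(node[0]), rec(node[1])
        out = []
        for s in range(4):
            best_l = min(lc[t] + (0 if t == s else 1) for t in range(4))
            best_r = min(rc[t] + (0 if t == s else 1) for t in range(4))
            out.append(best_l + best_r)
        return out

    return min(rec(tuple_tree))


@pytest.mark.parametrize("seed", range(8))
def test_fitch_matches_sankoff_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    ncols = int(rng.integers(5, 26))
    taxa = [f"t{i}" for i in range(n)]
    alphabet = list("ACGT-")
    rows = [
        "".join(rng.choice(alphabet, p=[0.23, 0.23, 0.23, 0.23, 0.08], size=ncols))
        for _ in taxa
    ]
    aln = MultipleAlignment(taxa, rows)
    tree = random_binary_tree(taxa, rng)
    tuple_tree = ph._pnode_to_tuple(ph._as_pnode(tree))
    expected = sum(
        _sankoff_min_steps(tuple_tree, {t: r[c] for t, r in zip(taxa, rows)})
        for c in range(ncols)
    )
    assert ph.fitch_score(tree, aln) == expected


# ------------------------------------------------------------------ MP search

def test_mp_matches_exhaustive_four_taxon_search():
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
    aln = MultipleAlignment(list("ABCD"), rows)
    exhaustive = min(
        ph.fitch_score(_tree(nwk), aln)
        for nwk in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
    )
    result = ph.mp_search(aln, n_random_addition=5, seed=1)
    assert result.score == exhaustive


def test_homoplasy_free_data_has_ci_one():
    # each informative column is a clean synapomorphy of a true clade
    aln = MultipleAlignment(
        ["a", "b", "c", "d", "e", "f"],
        [
            "AAAA",
            "AAAA",
            "TAAA",
            "TTAA",
            "TTTA",
            "TTTA",
        ],
    )
    result = ph.mp_search(aln, n_random_addition=10, seed=3)
    assert result.ci == 1.0


def test_mp_recovers_simulated_topology():
    newick = "((a:0.05,b:0.05):0.05,((c:0.05,d:0.05):0.05,(e:0.05,f:0.05):0.05):0.05);"
    aln = sd.simulate_alignment_on_tree(newick, length=600, seed=5)
    result = ph.mp_search(aln, n_random_addition=10, seed=7)
    assert any(ph.rf_distance(t, _tree(newick)) == 0 for t in result.best_trees)
    assert result.n_informative > 0


def test_mp_requires_four_taxa():
    aln = MultipleAlignment(["a", "b", "c"], ["A", "C", "G"])
    with pytest.raises(ValueError):
        ph.mp_search(aln, n_random_addition=1, seed=0)


# ------------------------------------------------- bootstrap and consensus

def test_consensus_keeps_edge_at_exactly_fifty_percent():
    resolved = _tree("((A,B),(C,D));")
    star = _tree("(A,B,C,D);")
    kept = ph.consensus_from_trees([resolved, star], collapse_below=50)
    assert ph.tree_splits(kept) == {frozenset({"C", "D"})}
    support = [n.label for n in kept.preorder_node_iter()
               if not n.is_leaf() and n.label]
    assert support == ["50"]


def test_consensus_collapses_edge_below_fifty_percent():
    resolved = _tree("((A,B),(C,D));")
    star = _tree("(A,B,C,D);")
    collapsed = ph.consensus_from_trees([resolved] * 49 + [star] * 51,
                                        collapse_below=50)
    assert ph.tree_splits(collapsed) == set()


def test_consensus_of_single_tree_is_that_tree():
    t = _tree("((A,B),((C,D),E));")
    cons = ph.consensus_from_trees([t], collapse_below=50)
    assert ph.rf_distance(cons, t) == 0


def test_bootstrap_is_seed_deterministic_and_supports_strong_clades():
    newick = ("((a:0.08,b:0.08):0.1,((c:0.08,d:0.08):0.1,"
              "(e:0.08,f:0.08):0.1):0.05);")
    aln = sd.simulate_alignment_on_tree(newick, length=800, seed=2)
    t1 = ph.bootstrap_consensus(aln, builder="nj", n_reps=100, seed=42)
    t2 = ph.bootstrap_consensus(aln, builder="nj", n_reps=100, seed=42)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
    splits = ph.tree_splits(t1)
    for clade in ({"a", "b"}, {"c", "d"}, {"e", "f"}):
        side = frozenset(clade)
        other = frozenset("abcdef") - side
        assert side in splits or other in splits
    supports = [float(n.label) for n in t1.preorder_node_iter()
                if not n.is_leaf() and n.label]
    assert supports and min(supports) >= 50.0


def test_bootstrap_rejects_zero_reps():
    aln = MultipleAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACTT"])
    with pytest.raises(ValueError):
        ph.bootstrap_consensus(aln, n_reps=0)


# -------------------------------------------------------------------------- RF

def test_rf_identical_and_alternative_quartets():
    t1, t2 = _tree("((A,B),(C,D));"), _tree("((A,C),(B,D));")
    assert ph.rf_distance(t1, t1) == 0
    assert ph.rf_distance(t1, t2) == 2


def test_rf_star_vs_resolved_counts_internal_edges():
    star = _tree("(A,B,C,D,E);")
    resolved = _tree("((A,B),((C,D),E));")
    assert ph.rf_distance(star, resolved) == 2


@pytest.mark.parametrize("seed", range(5))
def test_rf_matches_dendropy(seed):
    rng = np.random.default_rng(100 + seed)
    labels = [f"t{i}" for i in range(8)]
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=random_binary_tree(labels, rng).as_string(schema="newick"),
        schema="newick", taxon_namespace=ns, preserve_underscores=True)
    b = dendropy.Tree.get(
        data=random_binary_tree(labels, rng).as_string(schema="newick"),
        schema="newick", taxon_namespace=ns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    assert ph.rf_distance(a, b) == treecompare.symmetric_difference(a, b)


def test_rf_rejects_leaf_mismatch():
    with pytest.raises(Exception):
        ph.rf_distance(_tree("((A,B),(C,D));"), _tree("((A,B),(C,E));"))
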