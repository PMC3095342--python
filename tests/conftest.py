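"""Shared fixtures: small simulated genomes and random-tree helpers."""
from __future__ import annotations

import dendropy
import numpy as np
import pytest

from plastidmark import synthetic_data as sd


@pytest.fixture
def structure_cfg():
    """A gene-free, small quadripartite genome config for IR detection."""
    def make(seed: int, lsc=6000, ir=1500, ssc=1200):
        return sd.SimConfig(
            seed=seed, structure_lengths=(lsc, ir, ssc), gene_panel=[]
        )
    return make


@pytest.fixture
def small_panel_cfg():
    """A compact genome carrying three single-copy genes."""
    panel = [
        sd.GeneSpec("ndhC", 363, "LSC", "+"),
        sd.GeneSpec("ndhJ", 477, "LSC", "+"),
        sd.GeneSpec("ndhE", 306, "SSC", "-"),
    ]
    def make(seed: int):
        return sd.SimConfig(
            seed=seed, structure_lengths=(6000, 1500, 2000), gene_panel=panel
        )
    return make


def random_binary_tree(labels, rng, min_bl=0.1, max_bl=1.0) -> dendropy.Tree:
    """A random binary tree with uniform branch lengths (helper)."""
    def build(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        idx = rng.permutation(len(group))
        left = [group[i] for i in idx[:k]]
        right = [group[i] for i in idx[k:]]
        return f"({build(left)}:{rng.uniform(min_bl, max_bl):.4f}," \
               f"{build(right)}:{rng.uniform(min_bl, max_bl):.4f})"
    newick = build(list(labels)) + ";"
    return dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


def additive_matrix(tree: dendropy.Tree):
    """Taxa list and exact path-length distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], m
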