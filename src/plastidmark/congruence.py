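"""Congruence of marker trees with the maternal pedigree.

The plastome is maternally inherited, so taxa sharing a maternal founder
(reached by following female-parent links through the pedigree) must
form a clade in any correct plastid tree.  This module formalizes the
"correct placement" of a variety as maternal-group bipartition recovery,
scores trees accordingly, and ranks marker-region subsets by how well
their trees reproduce the full multi-region result -- the search for the
smallest marker set that identifies every variety.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import FormatError, MultipleAlignment, Pedigree, Tree
from .phylogeny import (
    build_nj,
    build_upgma,
    bootstrap_consensus,
    mp_search,
    pairwise_distances,
    rf_distance,
    tree_splits,
    _as_pnode,
)

__all__ = [
    "PlacementReport",
    "SubsetEvaluation",
    "maternal_groups",
    "placement_score",
    "evaluate_marker_subsets",
]


@dataclass
class PlacementReport:
    """Per-taxon correctness of a tree against the maternal pedigree."""

    per_taxon: dict[str, str]
    n_correct: int
    n_evaluated: int
    recovered_groups: list[str]

    def __post_init__(self) -> None:
        if not (self.n_correct <= self.n_evaluated <= len(self.per_taxon)):
            raise FormatError("inconsistent placement counts")


@dataclass
class SubsetEvaluation:
    """Outcome of evaluating one marker-region subset."""

    region_subset: tuple[str, ...]
    total_bp: int
    placement: PlacementReport
    rf_to_reference: int


def maternal_groups(
    pedigree: Pedigree, taxa: Optional[Sequence[str]] = None
) -> list[tuple[str, frozenset[str]]]:
    """Group taxa by maternal founder.

    Each taxon is assigned to the founder its female-parent chain
    terminates at.  Restricting to ``taxa`` (e.g. the sampled varieties)
    is typical; all pedigree entries are used otherwise.  Groups are
    returned sorted by founder name; groups of size >= 2 are the
    testable clades.
    """
    names = list(taxa) if taxa is not None else pedigree.varieties
    groups: dict[str, set[str]] = {}
    for name in names:
        groups.setdefault(pedigree.maternal_founder(name), set()).add(name)
    return [(f, frozenset(m)) for f, m in sorted(groups.items())]


def _steiner_attachment_nodes(tree: Tree, group: frozenset[str]):
    """Nodes of the minimal spanning subtree connecting ``group`` leaves,
    plus the attachment (parent-side) nodes of those leaves."""
    leaf_nodes = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon
    }
    members = [leaf_nodes[g] for g in group]
    # union of node paths between a fixed member and every other member
    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    base = path_to_root(members[0])
    base_index = {id(n): i for i, n in enumerate(base)}
    span = set()
    for other in members[1:]:
        path = []
        node = other
        while id(node) not in base_index:
            path.append(node)
            node = node.parent_node
        meet = base_index[id(node)]
        span.update(id(n) for n in path)
        span.update(id(n) for n in base[: meet + 1])
    span.update(id(m) for m in members)
    return span


def placement_score(tree: Tree, pedigree: Pedigree) -> PlacementReport:
    """Score a tree's congruence with maternal inheritance.

    A maternal group (size >= 2) is *recovered* when some edge of the
    unrooted tree bipartitions exactly that group from everything else;
    all members of a recovered group are correct, all members of an
    unrecovered group incorrect.  A taxon in a singleton group is
    correct unless it sits inside the minimal spanning subtree of some
    other group (an intruder breaking that group); if no group of size
    >= 2 exists at all, singletons are unevaluable.  The measure uses
    bipartitions only, so it is invariant under re-rooting.
    """
    leaves = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
    )
    known = set(pedigree.varieties)
    missing = [l for l in leaves if l not in known]
    if missing:
        raise FormatError(f"tree leaves absent from pedigree: {missing}")
    groups = maternal_groups(pedigree, taxa=leaves)
    multi = [(f, g) for f, g in groups if len(g) >= 2]
    splits = tree_splits(tree)
    n_leaves = len(leaves)

    def is_clade(group: frozenset[str]) -> bool:
        if len(group) in (1, n_leaves):
            return True
        if len(group) == n_leaves - 1:
            return True  # complement of a single leaf: always an edge
        return group in splits or (frozenset(leaves) - group) in splits

    per_taxon: dict[str, str] = {}
    recovered = []
    for founder, group in multi:
        ok = is_clade(group)
        if ok:
            recovered.append(founder)
        for t in group:
            per_taxon[t] = "correct" if ok else "incorrect"

    singletons = [(f, next(iter(g))) for f, g in groups if len(g) == 1]
    if singletons:
        if not multi:
            for _, t in singletons:
                per_taxon[t] = "unevaluable"
        else:
            leaf_parent = {
                lf.taxon.label: lf.parent_node
                for lf in tree.leaf_node_iter()
                if lf.taxon
            }
            for _, t in singletons:
                intruding = False
                for founder, group in multi:
                    span = _steiner_attachment_nodes(tree, group)
                    if id(leaf_parent[t]) in span:
                        intruding = True
                        break
                per_taxon[t] = "incorrect" if intruding else "correct"
    n_eval = sum(1 for v in per_taxon.values() if v != "unevaluable")
    n_correct = sum(1 for v in per_taxon.values() if v == "correct")
    return PlacementReport(
        per_taxon=per_taxon,
        n_correct=n_correct,
        n_evaluated=n_eval,
        recovered_groups=sorted(recovered),
    )


def _build_tree(
    supermatrix: MultipleAlignment,
    builder: str,
    n_reps: int,
    seed: Optional[int],
    model: str = "JC69",
) -> Tree:
    if n_reps and n_reps > 1:
        return bootstrap_consensus(
            supermatrix, builder=builder, n_reps=n_reps, seed=seed, model=model
        )
    if builder == "nj":
        return build_nj(pairwise_distances(supermatrix, model=model))
    if builder == "upgma":
        return build_upgma(pairwise_distances(supermatrix, model=model))
    if builder == "mp":
        return mp_search(supermatrix, n_random_addition=10, seed=seed).best_trees[0]
    raise ValueError(f"unknown builder {builder!r}")


def evaluate_marker_subsets(
    regions: dict[str, MultipleAlignment],
    pedigree: Pedigree,
    subsets="all",
    builder: str = "nj",
    n_reps: int = 0,
    seed: Optional[int] = None,
    max_subset_size: int = 3,
    model: str = "JC69",
) -> list[SubsetEvaluation]:
    """Rank marker-region subsets by congruence with the pedigree.

    A reference tree is first built from all regions; each candidate
    subset is concatenated, analysed with the same builder protocol, and
    scored by placement correctness and Robinson-Foulds distance to the
    reference.  ``subsets='all'`` enumerates every subset of size
    <= ``max_subset_size`` plus the full set (bootstrap per subset is
    optional via ``n_reps``).  Ranking: most correct placements first,
    then smallest RF, then fewest total bp.
    """
    from .marker_extraction import concatenate_supermatrix

    names = sorted(regions)
    if subsets == "all":
        chosen = [
            combo
            for size in range(1, min(max_subset_size, len(names)) + 1)
            for combo in itertools.combinations(names, size)
        ]
        full = tuple(names)
        if full not in chosen:
            chosen.append(full)
    else:
        chosen = [tuple(s) for s in subsets]
        for s in chosen:
            unknown = [r for r in s if r not in regions]
            if unknown:
                raise FormatError(f"unknown region names {unknown}")
            if not s:
                raise FormatError("empty region subset")

    reference_matrix = concatenate_supermatrix([regions[n] for n in names])
    reference_tree = _build_tree(reference_matrix, builder, n_reps, seed, model)

    results = []
    for subset in chosen:
        sm = concatenate_supermatrix([regions[n] for n in subset])
        tree = _build_tree(sm, builder, n_reps, seed, model)
        placement = placement_score(tree, pedigree)
        rf = rf_distance(tree, reference_tree)
        results.append(
            SubsetEvaluation(
                region_subset=subset,
                total_bp=sm.width,
                placement=placement,
                rf_to_reference=rf,
            )
        )
    results.sort(
        key=lambda ev: (
            -ev.placement.n_correct,
            ev.rf_to_reference,
            ev.total_bp,
            ev.region_subset,
        )
    )
    return results
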