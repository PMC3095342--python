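"""Distance and parsimony tree inference with bootstrap consensus.

Implements, at desk scale (tens of taxa), the classical methods used for
multi-locus plastid marker analysis: p/JC69 distances, neighbor-joining
and UPGMA, Fitch parsimony scoring, a heuristic maximum-parsimony search
(random taxon addition + NNI hill climbing), nonparametric bootstrap
with majority-rule consensus (collapsing branches below a support
threshold), and Robinson-Foulds distances.  All algorithms are
implemented here rather than delegated, so every tie-break and random
step is explicit and seedable; dendropy is used only as the tree
container for input/output.

Trees cross the public API as dendropy objects with bootstrap supports
stored as internal-node labels (integer percentages).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import dendropy
import numpy as np

from .core_io import FormatError, MultipleAlignment, Tree

__all__ = [
    "DistanceMatrix",
    "ParsimonyResult",
    "SaturationError",
    "pairwise_distances",
    "build_nj",
    "build_upgma",
    "fitch_score",
    "mp_search",
    "bootstrap_consensus",
    "consensus_from_trees",
    "tree_splits",
    "rf_distance",
]


class SaturationError(ValueError):
    """A pairwise p-distance is too large for the JC69 correction."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of substitutions/site between taxa."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if m.shape != (n, n):
            raise FormatError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise FormatError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise FormatError("distance matrix diagonal must be zero")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise FormatError("distances must be finite and non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_alignment(aln: MultipleAlignment) -> np.ndarray:
    """Rows as int8 codes: 0..3 = ACGT, -1 = missing (gap, N, ambiguity)."""
    out = np.full((len(aln.taxa), aln.width), -1, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for base, code in _BASE_CODES.items():
            out[i][arr == ord(base)] = code
    return out


def pairwise_distances(
    aln: MultipleAlignment, model: str = "JC69", gap_mode: str = "complete"
) -> DistanceMatrix:
    """p or Jukes-Cantor distances from an alignment.

    ``gap_mode='complete'`` excludes a column for all pairs as soon as
    any row has a gap/ambiguity there (the usual complete-deletion
    treatment); ``'pairwise'`` excludes columns per pair.  JC69 applies
    d = -(3/4) ln(1 - 4p/3) and raises :class:`SaturationError` for
    p >= 0.75, naming the offending pair.
    """
    if model not in ("p", "JC69"):
        raise ValueError(f"unknown model {model!r}")
    if gap_mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    enc = _encode_alignment(aln)
    n = len(aln.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    valid = enc >= 0
    if gap_mode == "complete":
        keep = valid.all(axis=0)
        enc = enc[:, keep]
        valid = valid[:, keep]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise FormatError(
                    f"no comparable sites between {aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = float((enc[i][both] != enc[j][both]).sum()) / sites
            if model == "p":
                d = p
            else:
                if p >= 0.75:
                    raise SaturationError(
                        f"JC69 saturated for pair ({aln.taxa[i]}, {aln.taxa[j]}): p={p:.3f}"
                    )
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(aln.taxa), m)


# ---------------------------------------------------------------------------
# Lightweight tree nodes (internal); dendropy at the API boundary
# ---------------------------------------------------------------------------

class _PNode:
    __slots__ = ("children", "label", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children: list[_PNode] = children or []
        self.length = length
        self.support = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            s = self.label
        else:
            s = "(" + ",".join(c._nwk() for c in self.children) + ")"
            if self.support is not None:
                s += f"{int(round(self.support))}"
        if self.length is not None:
            s += f":{self.length:.10g}"
        return s


def _to_dendropy(node: _PNode) -> Tree:
    return dendropy.Tree.get(
        data=node.newick(), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


def _from_dendropy(tree: Tree) -> _PNode:
    def convert(dn) -> _PNode:
        if dn.is_leaf():
            label = dn.taxon.label if dn.taxon else dn.label
            return _PNode(label=label, length=dn.edge.length)
        kids = [convert(c) for c in dn.child_nodes()]
        support = None
        if dn.label is not None:
            try:
                support = float(dn.label)
            except ValueError:
                pass
        return _PNode(children=kids, length=dn.edge.length, support=support)

    return convert(tree.seed_node)


def _as_pnode(tree) -> _PNode:
    return tree if isinstance(tree, _PNode) else _from_dendropy(tree)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _canonical_splits(node: _PNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each represented by the side *not*
    containing the reference taxon (the lexicographically first label)."""
    ref = min(taxa)
    splits: set[frozenset[str]] = set()

    def walk(n: _PNode) -> frozenset[str]:
        if n.is_leaf():
            return frozenset([n.label])
        below = frozenset().union(*(walk(c) for c in n.children))
        side = below if ref not in below else taxa - below
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
        return below

    walk(node)
    return splits


def tree_splits(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a tree (rooting-independent)."""
    node = _as_pnode(tree)
    return _canonical_splits(node, frozenset(node.leaves()))


def rf_distance(t1, t2) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    n1, n2 = _as_pnode(t1), _as_pnode(t2)
    l1, l2 = frozenset(n1.leaves()), frozenset(n2.leaves())
    if l1 != l2:
        raise FormatError("trees have different leaf sets")
    return len(_canonical_splits(n1, l1) ^ _canonical_splits(n2, l2))


# ---------------------------------------------------------------------------
# Neighbor joining / UPGMA
# ---------------------------------------------------------------------------

def _nj_node(taxa: Sequence[str], matrix: np.ndarray) -> _PNode:
    n = len(taxa)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes = [_PNode(label=t) for t in taxa]
    d = matrix.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin over row-major order
        idx = int(np.argmin(q))
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sister branch
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = _PNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node
        new_row = 0.5 * (d[ai, active] + d[aj, active] - dij)
        d[ai, active] = new_row
        d[np.ix_(active, [ai])] = new_row[:, None]
        d[ai, ai] = 0.0
        nodes[ai] = parent
        active.remove(aj)
    a, b = active
    mid = d[a, b]
    nodes[a].length = None
    # unrooted: attach the last two groups; put the full remaining length
    # on the second child so path lengths are preserved
    root = nodes[a]
    if root.is_leaf():
        root = _PNode(children=[nodes[a], nodes[b]])
        nodes[a].length = 0.0
        nodes[b].length = mid
    else:
        nodes[b].length = max(mid, 0.0)
        root.children.append(nodes[b])
    return root


def build_nj(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree (unrooted; trifurcating root node)."""
    return _to_dendropy(_nj_node(dm.taxa, dm.matrix))


def _upgma_node(taxa: Sequence[str], matrix: np.ndarray) -> _PNode:
    n = len(taxa)
    clusters: dict[int, tuple[_PNode, int, float]] = {
        i: (_PNode(label=t), 1, 0.0) for i, t in enumerate(taxa)
    }
    d = matrix.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                i, j = active[x], active[y]
                key = (d[i, j], i, j)
                if best is None or key < best:
                    best = key
        dij, i, j = best
        ni, si, hi = clusters[i]
        nj_, sj, hj = clusters[j]
        height = dij / 2.0
        ni.length = height - hi
        nj_.length = height - hj
        parent = _PNode(children=[ni, nj_])
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (si * d[i, k] + sj * d[j, k]) / (si + sj)
        clusters[i] = (parent, si + sj, height)
        active.remove(j)
    return clusters[active[0]][0]


def build_upgma(dm: DistanceMatrix) -> Tree:
    """UPGMA ultrametric rooted tree."""
    if len(dm.taxa) < 3:
        raise ValueError("UPGMA requires at least 3 taxa")
    return _to_dendropy(_upgma_node(dm.taxa, dm.matrix))


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

_MASKS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING_MASK = 15  # gaps and ambiguity codes: no cost (missing data)


def _leaf_masks(aln: MultipleAlignment) -> dict[str, np.ndarray]:
    out = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        mask = np.full(aln.width, _MISSING_MASK, dtype=np.uint8)
        for base, bit in _MASKS.items():
            mask[arr == ord(base)] = bit
        out[taxon] = mask
    return out


def _fitch_tuple(tree, masks) -> int:
    """Fitch steps of a nested-tuple tree; leaves are taxon labels."""

    def rec(node) -> tuple[np.ndarray, int]:
        if isinstance(node, str):
            return masks[node], 0
        left, right = node
        m1, s1 = rec(left)
        m2, s2 = rec(right)
        inter = m1 & m2
        zero = inter == 0
        steps = s1 + s2 + int(zero.sum())
        state = np.where(zero, m1 | m2, inter)
        return state, steps

    _, steps = rec(tree)
    return steps


def _pnode_to_tuple(node: _PNode):
    """Binarize (caterpillar on child order) and strip metadata."""
    if node.is_leaf():
        return node.label
    parts = [_pnode_to_tuple(c) for c in node.children]
    t = parts[0]
    for p in parts[1:]:
        t = (t, p)
    return t


def fitch_score(tree, aln: MultipleAlignment) -> int:
    """Parsimony steps of a tree on an alignment (Fitch counting).

    Gaps and ambiguity codes are missing data (never add steps).
    Multifurcations are resolved arbitrarily-but-deterministically before
    scoring.
    """
    node = _as_pnode(tree)
    leaves = node.leaves()
    if sorted(leaves) != sorted(aln.taxa):
        raise FormatError("tree leaves do not match alignment taxa")
    masks = _leaf_masks(aln)
    return _fitch_tuple(_pnode_to_tuple(node), masks)


def _tuple_leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _tuple_leaves(node[0]) + _tuple_leaves(node[1])


def _tuple_splits(node, taxa: frozenset[str]) -> frozenset[frozenset[str]]:
    ref = min(taxa)
    splits = set()

    def walk(n) -> frozenset:
        if isinstance(n, str):
            return frozenset([n])
        below = walk(n[0]) | walk(n[1])
        side = below if ref not in below else taxa - below
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
        return below

    walk(node)
    return frozenset(splits)


def _insert_everywhere(tree, leaf):
    """All trees obtained by attaching ``leaf`` on each edge of ``tree``."""
    results = [(tree, leaf)]
    if not isinstance(tree, str):
        left, right = tree
        results.extend((new, right) for new in _insert_everywhere(left, leaf))
        results.extend((left, new) for new in _insert_everywhere(right, leaf))
    return results


def _nni_neighbors(tree):
    """All NNI rearrangements of a rooted-tuple representation of an
    unrooted tree (root edge included once)."""
    out = []

    def rec(node, rebuild):
        if isinstance(node, str):
            return
        left, right = node
        if not isinstance(left, str):
            x, y = left
            out.append(rebuild(((x, right), y)))
            out.append(rebuild(((y, right), x)))
        if not isinstance(right, str):
            z, w = right
            out.append(rebuild((z, (w, left))))
            out.append(rebuild((w, (z, left))))
        rec(left, lambda sub: rebuild((sub, right)))
        rec(right, lambda sub: rebuild((left, sub)))

    # The edge between the root's two children is the same unrooted edge as
    # the root itself, so top-level swaps above cover it; recurse for the rest.
    rec(tree, lambda sub: sub)
    return out


@dataclass
class ParsimonyResult:
    """Outcome of a heuristic maximum-parsimony search."""

    best_trees: list[Tree]
    score: int
    n_informative: int
    ci: float
    ri: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci <= 1.0 and 0.0 <= self.ri <= 1.0):
            raise FormatError("CI and RI must lie in [0, 1]")


def _site_step_bounds(aln: MultipleAlignment):
    """Per-column (min_steps, max_steps, informative, n_valid)."""
    enc = _encode_alignment(aln)
    mins, maxs, informative = [], [], []
    for col in enc.T:
        counts = np.bincount(col[col >= 0], minlength=4)
        states = counts[counts > 0]
        if len(states) == 0:
            mins.append(0); maxs.append(0); informative.append(False)
            continue
        mins.append(len(states) - 1)
        maxs.append(int(states.sum() - states.max()))
        informative.append(int((states >= 2).sum()) >= 2)
    return np.array(mins), np.array(maxs), np.array(informative, dtype=bool)


def mp_search(
    aln: MultipleAlignment,
    n_random_addition: int = 100,
    seed: Optional[int] = None,
) -> ParsimonyResult:
    """Heuristic MP search: random addition sequences + NNI hill climbing.

    Each replicate builds a stepwise-addition starting tree from a random
    taxon order, then applies nearest-neighbor-interchange moves until no
    strictly better neighbor exists.  All distinct best-scoring
    topologies across replicates are returned.  The consistency index is
    computed over parsimony-informative characters; the retention index
    over all characters.
    """
    taxa = list(aln.taxa)
    if len(taxa) < 4:
        raise ValueError("MP search requires at least 4 taxa")
    masks = _leaf_masks(aln)
    rng = np.random.default_rng(seed)
    taxa_set = frozenset(taxa)

    best_score = None
    best_trees: dict[frozenset, tuple] = {}
    for _ in range(n_random_addition):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        tree = ((order[0], order[1]), order[2])
        for leaf in order[3:]:
            candidates = _insert_everywhere(tree, leaf)
            scored = [(_fitch_tuple(t, masks), k) for k, t in enumerate(candidates)]
            s, k = min(scored)
            tree = candidates[k]
        score = _fitch_tuple(tree, masks)
        improved = True
        while improved:
            improved = False
            for neighbor in _nni_neighbors(tree):
                s = _fitch_tuple(neighbor, masks)
                if s < score:
                    tree, score = neighbor, s
                    improved = True
                    break
        key = _tuple_splits(tree, taxa_set)
        if best_score is None or score < best_score:
            best_score = score
            best_trees = {key: tree}
        elif score == best_score and key not in best_trees:
            best_trees[key] = tree
    mins, maxs, informative = _site_step_bounds(aln)
    n_informative = int(informative.sum())

    def tuple_to_pnode(t) -> _PNode:
        if isinstance(t, str):
            return _PNode(label=t)
        return _PNode(children=[tuple_to_pnode(t[0]), tuple_to_pnode(t[1])])

    # score restricted to informative columns (uninformative ones always
    # realize their minimum, so subtract it)
    uninformative_steps = int(mins[~informative].sum())
    s_inf = best_score - uninformative_steps
    min_inf = int(mins[informative].sum())
    ci = 1.0 if s_inf == 0 else min_inf / s_inf
    tot_min, tot_max = int(mins.sum()), int(maxs.sum())
    ri = 1.0 if tot_max == tot_min else (tot_max - best_score) / (tot_max - tot_min)
    trees = [
        _to_dendropy(tuple_to_pnode(t))
        for _, t in sorted(best_trees.items(), key=lambda kv: sorted(map(sorted, kv[0])))
    ]
    return ParsimonyResult(
        best_trees=trees,
        score=int(best_score),
        n_informative=n_informative,
        ci=float(min(ci, 1.0)),
        ri=float(min(max(ri, 0.0), 1.0)),
    )


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------

def _resample(aln: MultipleAlignment, rng: np.random.Generator) -> MultipleAlignment:
    cols = rng.integers(0, aln.width, size=aln.width)
    byte_matrix = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
    rows = [row.tobytes().decode() for row in byte_matrix[:, cols]]
    return MultipleAlignment(list(aln.taxa), rows)


def _builder_splits(aln: MultipleAlignment, builder: str, model: str,
                    rng: np.random.Generator) -> frozenset:
    taxa = frozenset(aln.taxa)
    if builder == "nj":
        dm = pairwise_distances(aln, model=model)
        return frozenset(_canonical_splits(_nj_node(dm.taxa, dm.matrix), taxa))
    if builder == "upgma":
        dm = pairwise_distances(aln, model=model)
        return frozenset(_canonical_splits(_upgma_node(dm.taxa, dm.matrix), taxa))
    if builder == "mp":
        seed = int(rng.integers(0, 2**31 - 1))
        res = mp_search(aln, n_random_addition=2, seed=seed)
        return frozenset(tree_splits(res.best_trees[0]))
    raise ValueError(f"unknown builder {builder!r}")


def _splits_compatible(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def _tree_from_splits(
    taxa: Sequence[str], supported: list[tuple[frozenset, float]]
) -> Tree:
    """Build a (possibly multifurcating) tree from compatible canonical
    splits, attaching percent supports as internal labels."""
    root_set = frozenset(taxa)
    nodes = {root_set: _PNode()}
    for side, support in sorted(supported, key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        nodes[side] = _PNode(support=support)
    # parent = smallest strict superset
    sets = sorted(nodes, key=len)
    for s in sets:
        if s == root_set:
            continue
        parent = min(
            (t for t in nodes if len(t) > len(s) and s < t),
            key=len,
        )
        nodes[parent].children.append(nodes[s])
    for taxon in sorted(taxa):
        parent = min((t for t in nodes if taxon in t), key=len)
        nodes[parent].children.append(_PNode(label=taxon))
    return _to_dendropy(nodes[root_set])


def consensus_from_trees(trees: Sequence, collapse_below: float = 50.0) -> Tree:
    """Majority-rule consensus of replicate trees.

    A bipartition is retained when it appears in at least
    ``collapse_below`` percent of the replicates (so support exactly at
    the threshold survives, matching a strict "< threshold collapses"
    rule) and is compatible with every better-supported retained split.
    Supports are attached as integer percentages.
    """
    if not trees:
        raise ValueError("no replicate trees")
    pnodes = [_as_pnode(t) for t in trees]
    taxa = frozenset(pnodes[0].leaves())
    counts: dict[frozenset, int] = {}
    for pn in pnodes:
        if frozenset(pn.leaves()) != taxa:
            raise FormatError("replicate trees have differing leaf sets")
        for split in _canonical_splits(pn, taxa):
            counts[split] = counts.get(split, 0) + 1
    n = len(pnodes)
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0]))
    )
    kept: list[tuple[frozenset, float]] = []
    for split, count in ranked:
        pct = 100.0 * count / n
        if pct < collapse_below:
            continue
        if all(_splits_compatible(split, other) for other, _ in kept):
            kept.append((split, pct))
    return _tree_from_splits(sorted(taxa), kept)


def bootstrap_consensus(
    aln: MultipleAlignment,
    builder: str = "nj",
    n_reps: int = 1000,
    seed: Optional[int] = None,
    collapse_below: float = 50.0,
    model: str = "JC69",
) -> Tree:
    """Nonparametric bootstrap with majority-rule consensus.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate is analysed with the chosen builder (nj, upgma, or a short
    mp search); branches reproduced in fewer than ``collapse_below``
    percent of the replicates are collapsed, and retained branches carry
    their support percentage as the internal-node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = frozenset(aln.taxa)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        rep = _resample(aln, rng)
        for split in _builder_splits(rep, builder, model, rng):
            counts[split] = counts.get(split, 0) + 1
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0]))
    )
    kept: list[tuple[frozenset, float]] = []
    for split, count in ranked:
        pct = 100.0 * count / n_reps
        if pct < collapse_below:
            continue
        if all(_splits_compatible(split, other) for other, _ in kept):
            kept.append((split, pct))
    return _tree_from_splits(sorted(taxa), kept)
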