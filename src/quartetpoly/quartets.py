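"""Aggregated quartet-topology frequencies around species-tree branches.

For an internal branch B of the species tree, the four subtrees adjacent to B
partition the taxa into sets (L, R, S, O): the two child clades, the sister
clade, and the remainder.  A *quartet around B* takes one taxon from each set;
its induced topology in a gene tree is

* ``t1`` — the L-taxon with the R-taxon (agrees with the species tree),
* ``t2`` — the L-taxon with the S-taxon,
* ``t3`` — the L-taxon with the O-taxon,

or it is *unresolved* (a star in a multifurcating gene tree) or *missing*
(some taxon absent).  The default ``mean`` aggregation gives each gene tree j
a unit vote split proportionally to its resolved quartet counts n_{i,j}:

    f_{i,j} = n_{i,j} / (n_{1,j} + n_{2,j} + n_{3,j}),     n_i = sum_j f_{i,j}

Gene trees resolving no quartet around B are discarded for B, which is why the
effective number of genes varies from branch to branch.

The per-gene counts are obtained without enumerating quartets: a resolved
quartet ab|cd is witnessed exactly twice in a gene tree, once at each endpoint
of its internal path -- the node where a and b lie in different components
while c and d share a third component.  Summing a product of component-wise
leaf counts over all nodes and halving therefore yields exact O(N) counting
per gene tree and branch.  An explicit quartet enumerator with the same
contract lives in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Literal, Sequence

import dendropy

from .trees import canonical_clade, internal_edge_bipartitions

__all__ = [
    "BranchContext",
    "QuartetTally",
    "branch_context",
    "all_branch_contexts",
    "quartet_topology_of",
    "tally_branch",
    "all_branch_tallies",
]

Topology = Literal["t1", "t2", "t3", "unresolved", "missing"]


@dataclass(frozen=True)
class BranchContext:
    """The four disjoint taxon sets around an internal species-tree branch."""

    left: frozenset
    right: frozenset
    sister: frozenset
    rest: frozenset
    key: frozenset  # canonical clade identifying the branch

    def __post_init__(self):
        sets = (self.left, self.right, self.sister, self.rest)
        if any(not s for s in sets):
            raise ValueError("all four sets around a branch must be non-empty")
        union = self.left | self.right | self.sister | self.rest
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("the four sets around a branch must be disjoint")


@dataclass
class QuartetTally:
    """Aggregated quartet frequencies (n1, n2, n3) for one branch."""

    n1: float
    n2: float
    n3: float
    effective_n: int
    fractions: list[tuple[float, float, float]] | None = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return self.n1 + self.n2 + self.n3


# ---------------------------------------------------------------------------
# branch contexts


def _leafsets_of_children(node) -> list[frozenset]:
    return [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in node.child_nodes()]


def branch_context(species_tree: dendropy.Tree, edge: dendropy.Edge) -> BranchContext:
    """Build the (left, right, sister, rest) sets for one internal edge."""
    head, tail = edge.head_node, edge.tail_node
    if head.is_leaf() or tail is None:
        raise ValueError("branch contexts exist only for internal edges")
    all_taxa = frozenset(lf.taxon.label for lf in species_tree.leaf_node_iter())

    kids = _leafsets_of_children(head)
    left, right = kids[0], frozenset().union(*kids[1:])

    below = left | right
    if tail.parent_node is not None:
        others = [s for c, s in zip(tail.child_nodes(), _leafsets_of_children(tail)) if c is not head]
        sister = frozenset().union(*others)
        rest = all_taxa - below - sister
    else:
        # tail is the root: the split above B is given by the root's other
        # children (equivalently, by the sibling subtree when the root is
        # bifurcating) -- the standard unrooted treatment of the root branch.
        others = [c for c in tail.child_nodes() if c is not head]
        if len(others) == 1 and not others[0].is_leaf():
            sets = _leafsets_of_children(others[0])
        else:
            sets = [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in others]
        if len(sets) < 2:
            raise ValueError("branch has fewer than four non-empty sides")
        sister = sets[0]
        rest = frozenset().union(*sets[1:])
    if not sister or not rest:
        raise ValueError("branch has fewer than four non-empty sides")
    key = canonical_clade(below, all_taxa)
    return BranchContext(left, right, sister, rest, key)


def all_branch_contexts(species_tree: dendropy.Tree) -> dict[frozenset, BranchContext]:
    """Contexts for every internal branch of the (unrooted) species tree."""
    n_taxa = sum(1 for _ in species_tree.leaf_node_iter())
    if n_taxa < 4:
        raise ValueError("species tree must have at least 4 taxa")
    return {
        key: branch_context(species_tree, edge)
        for key, edge in internal_edge_bipartitions(species_tree).items()
    }


# ---------------------------------------------------------------------------
# gene-tree encoding and per-gene counting


class _GeneEncoding:
    """Per-node component bitmasks of a gene tree over a fixed taxon index."""

    __slots__ = ("full", "components")

    def __init__(self, tree: dendropy.Tree, index: dict[str, int]):
        comp_lists: list[list[int]] = []
        masks: dict[int, int] = {}
        root = tree.seed_node
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                masks[id(nd)] = 1 << index[nd.taxon.label]
                continue
            kid_masks = [masks[id(c)] for c in nd.child_nodes()]
            m = 0
            for km in kid_masks:
                m |= km
            masks[id(nd)] = m
            comp_lists.append(kid_masks)  # rest mask appended after full known
        self.full = masks[id(root)]
        # second pass: add the "rest of the tree" component where non-empty
        self.components = []
        for nd, kids in zip(
            (n for n in tree.postorder_node_iter() if not n.is_leaf()), comp_lists
        ):
            rest = self.full & ~masks[id(nd)]
            comps = kids + [rest] if rest else kids
            if len(comps) >= 3:
                self.components.append(comps)


def _pair_split_count(p: Sequence[int], q: Sequence[int], r: Sequence[int], s: Sequence[int]) -> int:
    """Quartets with the p/q taxa in different components and the r/s pair
    together in a third component, at one node."""
    m = len(p)
    srs = sum(r[k] * s[k] for k in range(m))
    total = 0
    for i in range(m - 1):
        for j in range(i + 1, m):
            cross = p[i] * q[j] + p[j] * q[i]
            if cross:
                total += cross * (srs - r[i] * s[i] - r[j] * s[j])
    return total


def _gene_counts(enc: _GeneEncoding, am: int, bm: int, cm: int, dm: int) -> tuple[int, int, int]:
    """Exact counts of resolved quartets of each topology around a branch."""
    if not (enc.full & am and enc.full & bm and enc.full & cm and enc.full & dm):
        return (0, 0, 0)
    t1 = t2 = t3 = 0
    for comps in enc.components:
        a = [(m & am).bit_count() for m in comps]
        b = [(m & bm).bit_count() for m in comps]
        c = [(m & cm).bit_count() for m in comps]
        d = [(m & dm).bit_count() for m in comps]
        t1 += _pair_split_count(a, b, c, d) + _pair_split_count(c, d, a, b)
        t2 += _pair_split_count(a, c, b, d) + _pair_split_count(b, d, a, c)
        t3 += _pair_split_count(a, d, b, c) + _pair_split_count(b, c, a, d)
    # each resolved quartet is witnessed at both endpoints of its internal path
    return (t1 // 2, t2 // 2, t3 // 2)


def _masks(ctx: BranchContext, index: dict[str, int]) -> tuple[int, int, int, int]:
    def mask(labels):
        m = 0
        for l in labels:
            m |= 1 << index[l]
        return m

    return mask(ctx.left), mask(ctx.right), mask(ctx.sister), mask(ctx.rest)


def _taxon_index(ctx_or_sets) -> dict[str, int]:
    labels = sorted(ctx_or_sets)
    return {l: i for i, l in enumerate(labels)}


def quartet_topology_of(gene_tree: dendropy.Tree, quartet: Sequence[str]) -> Topology:
    """Induced unrooted topology of one quartet (a, b, c, d) in a gene tree.

    ``t1`` means a,b on one side; ``missing`` if any taxon is absent from the
    gene tree; ``unresolved`` if the induced quartet is a star.
    """
    a, b, c, d = quartet
    if len({a, b, c, d}) != 4:
        raise ValueError("quartet taxa must be distinct")
    present = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    if not {a, b, c, d} <= present:
        return "missing"
    index = {l: i for i, l in enumerate(sorted(present))}
    enc = _GeneEncoding(gene_tree, index)
    counts = _gene_counts(enc, 1 << index[a], 1 << index[b], 1 << index[c], 1 << index[d])
    for name, n in zip(("t1", "t2", "t3"), counts):
        if n:
            return name
    return "unresolved"


# ---------------------------------------------------------------------------
# tallies


def _encode_genes(genes: Sequence[dendropy.Tree], index: dict[str, int]) -> list[_GeneEncoding]:
    return [_GeneEncoding(g, index) for g in genes]


def tally_branch(
    ctx: BranchContext,
    genes: Sequence[dendropy.Tree],
    method: Literal["mean", "single", "median"] = "mean",
    keep_fractions: bool = False,
    _encodings: list[_GeneEncoding] | None = None,
    _index: dict[str, int] | None = None,
) -> QuartetTally:
    """Aggregate quartet frequencies around one branch over a gene-tree set."""
    if len(genes) == 0 and not _encodings:
        raise ValueError("gene-tree set is empty")
    if _index is None:
        labels = set()
        for g in genes:
            labels.update(lf.taxon.label for lf in g.leaf_node_iter())
        labels.update(ctx.left | ctx.right | ctx.sister | ctx.rest)
        _index = _taxon_index(labels)
    if _encodings is None:
        _encodings = _encode_genes(genes, _index)
    am, bm, cm, dm = _masks(ctx, _index)

    if method == "single":
        picks = (min(ctx.left), min(ctx.right), min(ctx.sister), min(ctx.rest))
        sm = tuple(1 << _index[t] for t in picks)
        n = [0, 0, 0]
        eff = 0
        for enc in _encodings:
            counts = _gene_counts(enc, *sm)
            tot = sum(counts)
            if tot == 0:
                continue
            eff += 1
            for i in range(3):
                n[i] += counts[i]
        return QuartetTally(n[0], n[1], n[2], eff)

    if method == "median":
        return _median_tally(ctx, _encodings, _index)

    if method != "mean":
        raise ValueError(f"unknown aggregation method {method!r}")

    n1 = n2 = n3 = 0.0
    eff = 0
    fractions = [] if keep_fractions else None
    for enc in _encodings:
        c1, c2, c3 = _gene_counts(enc, am, bm, cm, dm)
        tot = c1 + c2 + c3
        if tot == 0:
            continue  # gene resolves no quartet around B: discard for B
        eff += 1
        f = (c1 / tot, c2 / tot, c3 / tot)
        n1 += f[0]
        n2 += f[1]
        n3 += f[2]
        if fractions is not None:
            fractions.append(f)
    return QuartetTally(n1, n2, n3, eff, fractions)


def _median_tally(ctx: BranchContext, encodings, index) -> QuartetTally:
    """Per-quartet gene counts m_{i,k}; componentwise median over quartets k.

    Only intended for small trees: enumerates every quartet around the branch.
    """
    from itertools import product

    m1, m2, m3 = [], [], []
    contributing = set()
    for a, b, c, d in product(sorted(ctx.left), sorted(ctx.right), sorted(ctx.sister), sorted(ctx.rest)):
        masks = (1 << index[a], 1 << index[b], 1 << index[c], 1 << index[d])
        k = [0, 0, 0]
        for j, enc in enumerate(encodings):
            counts = _gene_counts(enc, *masks)
            if sum(counts):
                contributing.add(j)
            for i in range(3):
                k[i] += counts[i]
        m1.append(k[0])
        m2.append(k[1])
        m3.append(k[2])
    return QuartetTally(median(m1), median(m2), median(m3), len(contributing))


def all_branch_tallies(
    species_tree: dendropy.Tree,
    genes: Sequence[dendropy.Tree],
    method: Literal["mean", "single", "median"] = "mean",
) -> dict[frozenset, QuartetTally]:
    """One tally per internal branch of the species tree; leaf edges skipped."""
    if len(genes) == 0:
        raise ValueError("gene-tree set is empty")
    contexts = all_branch_contexts(species_tree)
    labels = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    for g in genes:
        labels.update(lf.taxon.label for lf in g.leaf_node_iter())
    index = _taxon_index(labels)
    encodings = _encode_genes(genes, index)
    return {
        key: tally_branch(ctx, genes, method, _encodings=encodings, _index=index)
        for key, ctx in contexts.items()
    }
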