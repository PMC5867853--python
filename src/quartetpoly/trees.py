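"""Reading, writing and structural editing of phylogenetic trees.

Species trees and gene trees are held as :class:`dendropy.Tree` objects sharing
a :class:`dendropy.TaxonNamespace`.  Species-tree branch lengths are in
coalescent units (CU); gene-tree branch lengths are arbitrary and unused by the
polytomy test, which consumes topology only.

Internal-node labels are interpreted differently by tree kind, matching common
newick conventions: on gene trees they are branch support values (percent or
fraction scale, auto-detected); on species trees they are plain names kept for
output.  Support lives on ``edge.head_node.support`` (``None`` when absent).
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "read_species_tree",
    "read_gene_trees",
    "write_newick",
    "parse_newick",
    "detect_support_scale",
    "contract_low_support",
    "collapse_nonrejected",
    "resolve_arbitrarily",
    "internal_edge_bipartitions",
    "edge_leafset",
    "canonical_clade",
]


class NewickError(ValueError):
    """Raised for malformed newick input or invalid tree structure."""


def _as_stream(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    return io.StringIO(str(source))


def _check_unique_leaves(tree: dendropy.Tree, line: int | None = None) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        where = f" (tree on line {line})" if line else ""
        raise NewickError(f"duplicate leaf labels {dup}{where}")


def parse_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse a single newick string into an (internally unrooted) tree."""
    tree = _read_one(text, taxon_namespace, support=False, line=None)
    return tree


def _read_one(text, taxon_namespace, support: bool, line: int | None) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        where = f" on line {line}" if line else ""
        raise NewickError(f"malformed newick{where}: {exc}") from exc
    _check_unique_leaves(tree, line)
    if support:
        _labels_to_support(tree)
    else:
        for nd in tree.preorder_internal_node_iter():
            nd.support = None
    return tree


def _labels_to_support(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_internal_node_iter():
        sup = None
        if nd.label not in (None, ""):
            try:
                sup = float(nd.label)
            except ValueError:
                sup = None
        nd.support = sup


def read_species_tree(source) -> dendropy.Tree:
    """Read one species tree in newick; internal labels kept as names."""
    text = _as_stream(source).read()
    return _read_one(text, None, support=False, line=None)


def read_gene_trees(source, taxon_namespace: dendropy.TaxonNamespace | None = None) -> list[dendropy.Tree]:
    """Read gene trees, one newick per line; internal labels become supports.

    When ``taxon_namespace`` is supplied (normally the species tree's), any
    gene-tree leaf label absent from it raises :class:`NewickError`.
    """
    known = None
    if taxon_namespace is not None:
        known = {t.label for t in taxon_namespace}
    ns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    trees = []
    for i, raw in enumerate(_as_stream(source), start=1):
        text = raw.strip()
        if not text:
            continue
        if known is not None:
            # validate labels before dendropy silently grows the namespace
            probe = _read_one(text, None, support=False, line=i)
            for lf in probe.leaf_node_iter():
                if lf.taxon.label not in known:
                    raise NewickError(
                        f"gene tree on line {i} contains unknown taxon "
                        f"{lf.taxon.label!r} (not in the species tree)"
                    )
        trees.append(_read_one(text, ns, support=True, line=i))
    if not trees:
        raise NewickError("no gene trees found in input")
    return trees


def write_newick(tree: dendropy.Tree, dest=None, annotations: Mapping[frozenset, str] | None = None) -> str:
    """Serialize to newick; optionally write per-branch annotations.

    ``annotations`` maps canonical clades (see :func:`canonical_clade`) to
    strings placed as internal-node labels, the convention used for p-value
    annotated output.
    """
    if annotations:
        taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        all_taxa = frozenset(taxa)
        ref = taxa[0]
        for nd in tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            clade = canonical_clade(frozenset(l.taxon.label for l in nd.leaf_iter()), all_taxa, ref)
            if clade in annotations:
                nd.label = annotations[clade]
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if dest is not None:
        dest.write(text)
    return text


def canonical_clade(side: frozenset, all_taxa: frozenset, ref: str | None = None) -> frozenset:
    """Canonical representation of a bipartition: the side without ``ref``.

    ``ref`` defaults to the alphabetically smallest taxon, so both sides of a
    branch map to the same key regardless of rooting.
    """
    if ref is None:
        ref = min(all_taxa)
    return all_taxa - side if ref in side else side


def edge_leafset(edge: dendropy.Edge) -> frozenset:
    return frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())


def internal_edge_bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Edge]:
    """Map canonical clade -> edge for every internal branch of the unrooted tree.

    A branch is internal when both bipartition sides contain >=2 taxa.  The two
    rooted edges incident to a bifurcating root describe the same unrooted
    branch and are reported once.
    """
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_taxa)
    out: dict[frozenset, dendropy.Edge] = {}
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(below) < 2 or len(all_taxa - below) < 2:
            continue
        key = canonical_clade(below, all_taxa, ref)
        out.setdefault(key, nd.edge)
    return out


def detect_support_scale(trees: Iterable[dendropy.Tree]) -> str:
    """Return ``"fraction"`` when every support value is <= 1, else ``"percent"``."""
    seen = False
    for tree in trees:
        for nd in tree.preorder_internal_node_iter():
            sup = getattr(nd, "support", None)
            if sup is not None:
                seen = True
                if sup > 1.0:
                    return "percent"
    return "fraction" if seen else "percent"


def contract_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract internal edges whose support is at or below ``threshold``.

    Edges without a support value are never contracted.  Operates on a clone;
    the input is untouched.  The threshold is compared on the tree's own
    support scale.
    """
    if threshold < 0:
        raise ValueError("support threshold must be non-negative")
    out = tree.clone(depth=1)
    doomed = []
    for nd in out.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        sup = getattr(nd, "support", None)
        if sup is not None and sup <= threshold:
            doomed.append(nd.edge)
    for edge in doomed:
        edge.collapse()
    return out


def collapse_nonrejected(species_tree: dendropy.Tree, results: Mapping[frozenset, object], alpha: float) -> dendropy.Tree:
    """Contract every internal branch whose polytomy test was not rejected.

    ``results`` maps canonical clades to objects exposing ``p_value`` and
    ``applicable`` (see :mod:`quartetpoly.polytomy`).  Branches with
    ``p_value > alpha``, flagged not applicable, or absent from ``results``
    are contracted into polytomies.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = species_tree.clone(depth=1)
    all_taxa = frozenset(lf.taxon.label for lf in out.leaf_node_iter())
    ref = min(all_taxa)
    doomed_keys = set()
    for key in internal_edge_bipartitions(out):
        res = results.get(key)
        if res is None or not res.applicable or res.p_value > alpha:
            doomed_keys.add(key)
    # collapse every rooted edge representing a doomed unrooted branch (a
    # bifurcating root sits on one branch represented by both root edges)
    doomed = []
    for nd in out.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if canonical_clade(below, all_taxa, ref) in doomed_keys:
            doomed.append(nd.edge)
    for edge in doomed:
        edge.collapse()
    return out


def resolve_arbitrarily(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Refine every polytomy into an arbitrary binary resolution.

    Introduced edges have length 0, so the refined tree is statistically
    identical to the input under the coalescent.  Deterministic for a given
    seed; a binary input is returned unchanged (as a clone).
    """
    import random

    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for nd in list(out.preorder_internal_node_iter()):
        while len(nd._child_nodes) > 2:
            kids = list(nd._child_nodes)
            rng.shuffle(kids)
            a, b = kids[0], kids[1]
            joint = dendropy.Node()
            joint.support = None
            for c in (a, b):
                nd.remove_child(c)
                joint.add_child(c)
            joint.edge.length = 0.0
            nd.add_child(joint)
    return out
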