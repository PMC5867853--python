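"""Coalescent gene-tree simulation and the simulation-study fixtures.

The simulator works directly in coalescent units (CU): within a species-tree
branch of length x carrying k lineages, the next coalescence waits an
exponential time with rate k(k-1)/2, and lineages surviving to the root
coalesce freely above it.  Zero-length branches therefore behave exactly like
hard polytomies.  Only gene-tree topologies matter downstream, so CU fully
determines the simulated distribution; generation/population-size inputs are
converted at the boundary.

Also here: a Yule species-tree generator with a height cap (heights measured
in generations, output scaled to CU), two 12-taxon fixture trees containing
hard polytomies plus short focal branches, and a replicated
rejection-experiment runner used for type-I-error and power studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .polytomy import MIN_EFFECTIVE_N, polytomy_pvalue, chi2_statistic
from .quartets import _GeneEncoding, _taxon_index, all_branch_contexts, tally_branch
from .trees import (
    canonical_clade,
    internal_edge_bipartitions,
    parse_newick,
    resolve_arbitrarily,
)

__all__ = [
    "SimConfig",
    "simulate_gene_trees",
    "yule_species_tree",
    "s12_fixture",
    "unrooted_branch_lengths",
    "run_rejection_experiment",
]


@dataclass
class SimConfig:
    """Simulation setup: a species tree in CU (or a per-replicate factory),
    genes per replicate, replicate count, and the master seed."""

    species_tree: dendropy.Tree | Callable[[int], dendropy.Tree]
    n_genes: int
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")

    def tree_for(self, replicate: int) -> dendropy.Tree:
        if callable(self.species_tree):
            return self.species_tree(replicate)
        return self.species_tree


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    """Age above the leaf level for every node (leaves at 0)."""
    ages: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[id(nd)] = 0.0
        else:
            ages[id(nd)] = max(
                ages[id(c)] + (c.edge.length or 0.0) for c in nd.child_nodes()
            )
    return ages


def _coalesce(pool: list, t: float, span: float, rng: np.random.Generator):
    """Merge lineages in ``pool`` along a branch starting at age ``t`` for
    ``span`` CU (math.inf above the root).  Returns the updated age."""
    k = len(pool)
    while k > 1:
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait > span:
            return
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        parent = dendropy.Node()
        parent.age = t
        a, b = pool[i], pool[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.age
        b.edge.length = t - b.age
        lo, hi = (i, j) if i < j else (j, i)
        pool[hi] = pool[-1]
        pool.pop()
        pool[lo] = parent
        k -= 1


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    n_genes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[dendropy.Tree]:
    """Simulate independent error-free gene trees under the MSC.

    The species tree must carry CU branch lengths (zero allowed; the root
    edge is ignored).  Gene trees share the species tree's taxon namespace
    and have one sample per species.  Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    for nd in species_tree.preorder_node_iter():
        if nd.parent_node is not None and (nd.edge.length or 0.0) < 0:
            raise ValueError("species-tree branch lengths must be >= 0")
    ages = _node_ages(species_tree)
    ns = species_tree.taxon_namespace
    sp_postorder = list(species_tree.postorder_node_iter())

    out = []
    inf = float("inf")
    for _ in range(n_genes):
        pools: dict[int, list] = {}
        for nd in sp_postorder:
            if nd.is_leaf():
                tip = dendropy.Node(taxon=nd.taxon)
                tip.age = ages[id(nd)]
                pool = [tip]
            else:
                pool = []
                for c in nd.child_nodes():
                    pool.extend(pools.pop(id(c)))
            span = inf if nd.parent_node is None else ages[id(nd.parent_node)]
            _coalesce(pool, ages[id(nd)], span, rng)
            pools[id(nd)] = pool
        (root,) = pools[id(species_tree.seed_node)]
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = root
        tree.is_rooted = True  # genuinely rooted by coalescent time
        out.append(tree)
    return out


def yule_species_tree(
    n_taxa: int,
    birth_rate: float,
    max_height: float,
    pop_size: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """Pure-birth species tree, height capped, branch lengths in CU.

    ``birth_rate`` is per lineage per generation and ``max_height`` is in
    generations; the finished ultrametric tree is divided by ``pop_size`` to
    express branches in coalescent units.  Starting from the two crown
    lineages, inter-speciation waits are Exp(k·rate); after the last split an
    Exp(n·rate) observation time is appended, and realizations taller than
    the cap are rescaled onto it, so slow-speciation settings produce trees
    sitting exactly at the cap.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if birth_rate <= 0 or max_height <= 0 or pop_size <= 0:
        raise ValueError("birth_rate, max_height and pop_size must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    t = 0.0
    # (parent node, birth time) for each open lineage; speciation turns a
    # lineage into an internal node carrying two fresh lineages
    tips: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    while len(tips) < n_taxa:
        k = len(tips)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent, born = tips[i]
        node = dendropy.Node()
        node.time = t
        parent.add_child(node)
        node.edge.length = t - born
        tips[i] = (node, t)
        tips.append((node, t))
    present = t + rng.exponential(1.0 / (n_taxa * birth_rate))
    scale = 1.0 if present <= max_height else max_height / present
    for i, (parent, born) in enumerate(tips):
        leaf = dendropy.Node(taxon=ns.new_taxon(label=f"s{i + 1}"))
        parent.add_child(leaf)
        leaf.edge.length = present - born
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    factor = scale / pop_size
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= factor
    return tree


_S12A = (
    "((((t1:2.8,t2:2.8,(t3:1.0,t4:1.0):1.8):0.2,"
    "(t5:2.0,(t6:1.0,t7:1.0):1.0):1.0,t8:3.0):3.0,t9:6.0):2.0,"
    "(t10:4.0,(t11:2.0,t12:2.0):2.0):4.0);"
)

_S12B = (
    "(((t1:3.0,t2:3.0,(t3:1.0,t4:1.0):2.0,(t5:1.0,t6:1.0):2.0,"
    "(t7:1.0,t8:1.0):2.0):2.0,t9:5.0):3.0,"
    "(t10:4.0,(t11:2.0,t12:2.0):2.0):4.0);"
)


def s12_fixture(variant: str) -> tuple[dendropy.Tree, dict[str, frozenset]]:
    """12-taxon fixture species trees with hard polytomies (height 8 CU).

    Variant ``"A"`` has two 3-child polytomies, a 0.2 CU focal branch ``P0``
    (the parent edge of one polytomy) and a 1 CU focal branch ``P3``.
    Variant ``"B"`` has one 5-child polytomy and a 2 CU focal branch ``P7``
    adjacent to it.  Branch lengths not pinned down by those features are
    package constants chosen to keep every non-focal branch at >= 1 CU, so
    the focal branches dominate the local coalescent signal.

    Returns the tree and a map from focal-branch name to its canonical clade;
    entries ``polytomy1``/``polytomy2`` give the clades of the polytomy nodes
    themselves.
    """
    all_taxa = frozenset(f"t{i}" for i in range(1, 13))

    def clade(*taxa):
        return canonical_clade(frozenset(taxa), all_taxa)

    if variant.upper() == "A":
        tree = parse_newick(_S12A)
        focal = {
            "P0": clade("t1", "t2", "t3", "t4"),
            "P3": clade("t5", "t6", "t7"),
            "polytomy1": clade("t1", "t2", "t3", "t4"),
            "polytomy2": clade("t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8"),
        }
    elif variant.upper() == "B":
        tree = parse_newick(_S12B)
        focal = {
            "P7": clade(*[f"t{i}" for i in range(1, 9)]),
            "polytomy1": clade(*[f"t{i}" for i in range(1, 9)]),
        }
    else:
        raise ValueError("variant must be 'A' or 'B'")
    return tree, focal


def unrooted_branch_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """CU length of every internal branch of the unrooted topology.

    With a bifurcating root, the two rooted root edges form a single unrooted
    branch whose length is their sum.
    """
    root = tree.seed_node
    root_kids = root.child_nodes()
    root_sum = sum((c.edge.length or 0.0) for c in root_kids)
    out = {}
    for key, edge in internal_edge_bipartitions(tree).items():
        nd = edge.head_node
        if nd.parent_node is root and len(root_kids) == 2:
            out[key] = root_sum
        else:
            out[key] = edge.length or 0.0
    return out


def run_rejection_experiment(
    config: SimConfig,
    gene_counts: Sequence[int] | None = None,
    alpha: float = 0.05,
    length_range: tuple[float, float] | None = None,
    resolve_polytomies: bool = True,
) -> pd.DataFrame:
    """Replicated simulation study of the polytomy test.

    Per replicate: draw/take the species tree, arbitrarily resolve any
    polytomy (new edges have length 0, so the null is true for them),
    simulate ``config.n_genes`` true gene trees, subsample without
    replacement to each requested gene count, and test every internal branch
    (optionally only those whose true CU length falls in ``length_range``;
    resolution edges count as length 0).

    Returns a tidy frame with one row per (replicate, branch, gene count):
    columns ``replicate, clade, true_length, novel, n_genes, effective_n,
    chi2, p_value, applicable, rejected``.  Rejection requires both p <=
    alpha and the branch being applicable (effective n >= 10).
    """
    if gene_counts is None:
        gene_counts = [config.n_genes]
    if max(gene_counts) > config.n_genes:
        raise ValueError("gene_counts cannot exceed the simulated number of genes")
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.n_replicates)
    rows = []
    for rep, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        sp = config.tree_for(rep)
        true_lengths = unrooted_branch_lengths(sp)
        if resolve_polytomies:
            resolved = resolve_arbitrarily(sp, seed=int(rng.integers(2**31)))
        else:
            resolved = sp
        genes = simulate_gene_trees(resolved, config.n_genes, rng=rng)

        contexts = all_branch_contexts(resolved)
        lengths = {
            key: true_lengths.get(key, 0.0) for key in contexts
        }
        if length_range is not None:
            lo, hi = length_range
            contexts = {
                k: v for k, v in contexts.items() if lo <= lengths[k] <= hi
            }
        if not contexts:
            continue
        labels = {lf.taxon.label for lf in resolved.leaf_node_iter()}
        index = _taxon_index(labels)
        encodings = [_GeneEncoding(g, index) for g in genes]
        for count in gene_counts:
            if count == config.n_genes:
                chosen = encodings
            else:
                idx = rng.choice(config.n_genes, size=count, replace=False)
                chosen = [encodings[i] for i in idx]
            for key, ctx in contexts.items():
                tally = tally_branch(ctx, (), _encodings=chosen, _index=index)
                if tally.effective_n == 0:
                    chi2 = float("nan")
                    p = float("nan")
                    applicable = False
                else:
                    chi2 = chi2_statistic(tally)
                    p = polytomy_pvalue(chi2)
                    applicable = tally.effective_n >= MIN_EFFECTIVE_N
                rows.append(
                    {
                        "replicate": rep,
                        "clade": "|".join(sorted(key)),
                        "true_length": lengths[key],
                        "novel": key not in true_lengths,
                        "n_genes": count,
                        "effective_n": tally.effective_n,
                        "chi2": chi2,
                        "p_value": p,
                        "applicable": applicable,
                        "rejected": bool(applicable and p <= alpha),
                    }
                )
    return pd.DataFrame(rows)


def bin_rejection_by_length(
    table: pd.DataFrame, n_bins: int = 20
) -> pd.DataFrame:
    """Percent of branches rejected per log-length bin (equisized bins).

    Mirrors the long-branch power summary: branches are binned by the log of
    their true CU length into ``n_bins`` bins with (approximately) equal
    branch counts, separately for each gene count.
    """
    df = table[table["true_length"] > 0].copy()
    if df.empty:
        return pd.DataFrame(columns=["n_genes", "bin", "length_lo", "length_hi", "n_branches", "pct_rejected"])
    df["log_len"] = np.log(df["true_length"])
    out = []
    for count, sub in df.groupby("n_genes"):
        ranks = sub["log_len"].rank(method="first")
        sub = sub.assign(bin=np.ceil(ranks * n_bins / len(sub)).astype(int))
        for b, binned in sub.groupby("bin"):
            out.append(
                {
                    "n_genes": count,
                    "bin": b,
                    "length_lo": float(binned["true_length"].min()),
                    "length_hi": float(binned["true_length"].max()),
                    "n_branches": len(binned),
                    "pct_rejected": 100.0 * binned["rejected"].mean(),
                }
            )
    return pd.DataFrame(out)
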