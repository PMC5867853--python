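import io

import dendropy
import numpy as np
import pytest

import quartetpoly as qp


@pytest.fixture
def four_taxon_sp():
    """4-taxon species tree whose single unrooted internal branch is 1 CU."""
    return qp.read_species_tree("((a:1,b:1):0.5,(c:1,d:1):0.5);")


@pytest.fixture
def gene_set_721(four_taxon_sp):
    """10 complete binary gene trees: 7 t1, 2 t2, 1 t3."""
    text = "((a,b),(c,d));\n" * 7 + "((a,c),(b,d));\n" * 2 + "((a,d),(b,c));\n"
    return qp.read_gene_trees(io.StringIO(text), taxon_namespace=four_taxon_sp.taxon_namespace)


@pytest.fixture
def six_taxon_sp():
    return qp.read_species_tree(
        "(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);"
    )


def random_binary_gene_trees(species_tree, n_genes, seed):
    """Complete binary gene trees via the coalescent (topologies vary)."""
    return qp.simulate_gene_trees(species_tree, n_genes, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


# ---------------------------------------------------------------------------
# independent oracle: induced quartet topology via explicit bipartition checks


def oracle_quartet_topology(gene_tree: dendropy.Tree, a, b, c, d):
    """Induced topology of {a,b,c,d} by scanning clades for a separating edge."""
    present = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    if not {a, b, c, d} <= present:
        return "missing"
    quartet = {a, b, c, d}
    for nd in gene_tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()} & quartet
        other = quartet - side
        for name, pair in (("t1", {a, b}), ("t2", {a, c}), ("t3", {a, d})):
            if side == pair or other == pair:
                return name
    return "unresolved"


def oracle_mean_tally(ctx, genes):
    """Brute-force mean aggregation: enumerate every quartet around the branch."""
    from itertools import product

    n = [0.0, 0.0, 0.0]
    eff = 0
    names = ("t1", "t2", "t3")
    for g in genes:
        counts = [0, 0, 0]
        for quartet in product(sorted(ctx.left), sorted(ctx.right), sorted(ctx.sister), sorted(ctx.rest)):
            topo = oracle_quartet_topology(g, *quartet)
            if topo in names:
                counts[names.index(topo)] += 1
        tot = sum(counts)
        if tot == 0:
            continue
        eff += 1
        for i in range(3):
            n[i] += counts[i] / tot
    return n, eff
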