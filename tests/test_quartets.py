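"""Quartet topology classification and per-branch tallies.

The fast counter is checked against an explicit enumerate-every-quartet
oracle (see conftest), which is the defining computation of the mean
aggregation.
"""

import io
import itertools

import pytest

import quartetpoly as qp
from quartetpoly.quartets import all_branch_contexts, quartet_topology_of, tally_branch
from quartetpoly.trees import parse_newick

from conftest import oracle_mean_tally, oracle_quartet_topology, random_binary_gene_trees


def genes_from(text, sp=None):
    ns = sp.taxon_namespace if sp is not None else None
    return qp.read_gene_trees(io.StringIO(text), taxon_namespace=ns)


class TestQuartetTopology:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("((a,b),(c,d));", "t1"),
            ("((a,c),(b,d));", "t2"),
            ("((a,d),(b,c));", "t3"),
            ("(a,b,c,d);", "unresolved"),
            ("((a,b),(c,e));", "missing"),
        ],
    )
    def test_examples(self, newick, expected):
        g = parse_newick(newick)
        assert quartet_topology_of(g, ("a", "b", "c", "d")) == expected

    def test_duplicate_taxa_rejected(self):
        g = parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            quartet_topology_of(g, ("a", "a", "c", "d"))

    def test_embedded_quartet_in_larger_tree(self):
        g = parse_newick("(((a,x),(b,y)),((c,z),(d,w)));")
        assert quartet_topology_of(g, ("a", "b", "c", "d")) == "t1"
        assert quartet_topology_of(g, ("a", "c", "b", "d")) == "t2"

    def test_matches_oracle_on_random_trees(self, six_taxon_sp):
        genes = random_binary_gene_trees(six_taxon_sp, 10, seed=5)
        taxa = sorted(lf.taxon.label for lf in six_taxon_sp.leaf_node_iter())
        for g in genes:
            for quartet in itertools.combinations(taxa, 4):
                assert quartet_topology_of(g, quartet) == oracle_quartet_topology(g, *quartet)


class TestBranchContexts:
    def test_four_taxon_tree_has_one_branch(self, four_taxon_sp):
        ctxs = all_branch_contexts(four_taxon_sp)
        assert len(ctxs) == 1
        ctx = next(iter(ctxs.values()))
        sets = [ctx.left, ctx.right, ctx.sister, ctx.rest]
        assert sorted(map(sorted, sets)) == [["a"], ["b"], ["c"], ["d"]]

    def test_internal_branch_count_matches_n_minus_3(self):
        t, _ = qp.s12_fixture("B")
        resolved = qp.resolve_arbitrarily(t, seed=0)
        assert len(all_branch_contexts(resolved)) == 12 - 3

    def test_sets_partition_taxa_on_binary_trees(self, six_taxon_sp):
        taxa = {lf.taxon.label for lf in six_taxon_sp.leaf_node_iter()}
        for ctx in all_branch_contexts(six_taxon_sp).values():
            assert ctx.left | ctx.right | ctx.sister | ctx.rest == taxa

    def test_too_few_taxa_rejected(self):
        t = parse_newick("((a,b),c);")
        with pytest.raises(ValueError):
            all_branch_contexts(t)


class TestTallies:
    def test_four_taxon_counts(self, four_taxon_sp, gene_set_721):
        tally = next(iter(qp.all_branch_tallies(four_taxon_sp, gene_set_721).values()))
        assert (tally.n1, tally.n2, tally.n3) == (7.0, 2.0, 1.0)
        assert tally.effective_n == 10

    def test_gene_missing_a_whole_side_is_discarded(self, four_taxon_sp):
        genes = genes_from("((a,b),(c,d));\n((a,b),c);\n", four_taxon_sp)
        tally = next(iter(qp.all_branch_tallies(four_taxon_sp, genes).values()))
        assert tally.effective_n == 1
        assert tally.total == pytest.approx(1.0)

    def test_unresolved_quartet_counts_to_neither(self, four_taxon_sp):
        genes = genes_from("((a,b),(c,d));\n(a,b,c,d);\n", four_taxon_sp)
        tally = next(iter(qp.all_branch_tallies(four_taxon_sp, genes).values()))
        assert tally.effective_n == 1
        assert tally.n1 == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_contributing_gene(self, six_taxon_sp):
        genes = random_binary_gene_trees(six_taxon_sp, 12, seed=9)
        ctx = next(iter(all_branch_contexts(six_taxon_sp).values()))
        tally = tally_branch(ctx, genes, keep_fractions=True)
        assert tally.effective_n == 12
        for f in tally.fractions:
            assert sum(f) == pytest.approx(1.0)
        assert tally.total == pytest.approx(tally.effective_n)

    def test_gene_order_is_irrelevant(self, six_taxon_sp):
        genes = random_binary_gene_trees(six_taxon_sp, 15, seed=2)
        ctx = next(iter(all_branch_contexts(six_taxon_sp).values()))
        fwd = tally_branch(ctx, genes)
        rev = tally_branch(ctx, genes[::-1])
        assert (fwd.n1, fwd.n2, fwd.n3) == pytest.approx((rev.n1, rev.n2, rev.n3))

    def test_swapping_sister_and_rest_swaps_t2_t3(self, six_taxon_sp):
        genes = random_binary_gene_trees(six_taxon_sp, 15, seed=4)
        ctx = next(iter(all_branch_contexts(six_taxon_sp).values()))
        swapped = qp.BranchContext(ctx.left, ctx.right, ctx.rest, ctx.sister, ctx.key)
        a = tally_branch(ctx, genes)
        b = tally_branch(swapped, genes)
        assert (a.n1, a.n2, a.n3) == pytest.approx((b.n1, b.n3, b.n2))

    def test_empty_gene_set_rejected(self, six_taxon_sp):
        ctx = next(iter(all_branch_contexts(six_taxon_sp).values()))
        with pytest.raises(ValueError):
            tally_branch(ctx, [])


class TestOracleEquivalence:
    """The fast counter must reproduce explicit quartet enumeration exactly."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_tally_on_complete_binary_genes(self, seed):
        sp = qp.yule_species_tree(8, 1e-6, 2e6, 2e5, seed=100 + seed)
        genes = random_binary_gene_trees(sp, 20, seed=seed)
        for key, ctx in all_branch_contexts(sp).items():
            fast = tally_branch(ctx, genes)
            (o1, o2, o3), eff = oracle_mean_tally(ctx, genes)
            assert fast.effective_n == eff
            assert fast.n1 == pytest.approx(o1, abs=1e-9)
            assert fast.n2 == pytest.approx(o2, abs=1e-9)
            assert fast.n3 == pytest.approx(o3, abs=1e-9)

    def test_mean_tally_with_missing_and_unresolved_genes(self, six_taxon_sp):
        genes = genes_from(
            "(((a,b),(c,d)),(e,f));\n"
            "((a,b),(c,e));\n"           # d, f missing
            "(a,c,e,(b,(d,f)));\n"       # partially unresolved
            "((a,b),(e,f));\n"           # c, d missing
            "(a,b,c);\n",                # no quartet around any branch
            six_taxon_sp,
        )
        for ctx in all_branch_contexts(six_taxon_sp).values():
            fast = tally_branch(ctx, genes)
            (o1, o2, o3), eff = oracle_mean_tally(ctx, genes)
            assert fast.effective_n == eff
            assert (fast.n1, fast.n2, fast.n3) == pytest.approx((o1, o2, o3), abs=1e-9)

    def test_all_branch_tallies_equals_per_branch_calls(self, six_taxon_sp):
        genes = random_binary_gene_trees(six_taxon_sp, 10, seed=8)
        whole = qp.all_branch_tallies(six_taxon_sp, genes)
        for key, ctx in all_branch_contexts(six_taxon_sp).items():
            solo = tally_branch(ctx, genes)
            got = whole[key]
            assert (got.n1, got.n2, got.n3, got.effective_n) == (
                pytest.approx(solo.n1), pytest.approx(solo.n2),
                pytest.approx(solo.n3), solo.effective_n,
            )


class TestAlternativeAggregations:
    def test_single_uses_one_fixed_quartet(self, four_taxon_sp, gene_set_721):
        ctx = next(iter(all_branch_contexts(four_taxon_sp).values()))
        tally = tally_branch(ctx, gene_set_721, method="single")
        assert (tally.n1, tally.n2, tally.n3) == (7, 2, 1)

    def test_all_methods_agree_on_four_taxa(self, four_taxon_sp, gene_set_721):
        ctx = next(iter(all_branch_contexts(four_taxon_sp).values()))
        for method in ("mean", "single", "median"):
            tally = tally_branch(ctx, gene_set_721, method=method)
            assert (tally.n1, tally.n2, tally.n3) == (7, 2, 1)

    def test_mean_equals_mean_over_quartets_for_complete_genes(self, six_taxon_sp):
        # with complete binary gene trees the per-gene fractions reduce to
        # averaging the per-quartet indicator counts
        from itertools import product

        genes = random_binary_gene_trees(six_taxon_sp, 10, seed=3)
        ctx = next(iter(all_branch_contexts(six_taxon_sp).values()))
        tally = tally_branch(ctx, genes)
        quartets = list(product(sorted(ctx.left), sorted(ctx.right), sorted(ctx.sister), sorted(ctx.rest)))
        names = ("t1", "t2", "t3")
        m = {name: [] for name in names}
        for q in quartets:
            counts = dict.fromkeys(names, 0)
            for g in genes:
                topo = oracle_quartet_topology(g, *q)
                counts[topo] += 1
            for name in names:
                m[name].append(counts[name])
        expected = [sum(m[name]) / len(quartets) for name in names]
        assert (tally.n1, tally.n2, tally.n3) == pytest.approx(expected)
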