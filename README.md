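# quartetpoly

A statistical test for **polytomies in species trees** from gene-tree quartet
frequencies, for phylogenomics practitioners working with multi-locus data
(summary methods such as ASTRAL, and anyone asking "is this branch real, or
should it be a polytomy?").

## The test

For a quartet of species the multi-species coalescent (MSC) says a gene tree
matches the species-tree topology with probability p₁ = 1 − (2/3)e^(−x) and
each alternative with p₂ = p₃ = (1/3)e^(−x), where *x* is the internal branch
length in coalescent units (CU = generations / haploid population size).
A zero-length branch — a hard polytomy — makes all three topologies
equifrequent, so for each internal branch *B* of a species tree we test

> **H₀:** the gene-tree quartets around *B* support all three resolutions in
> equal numbers

with a chi-squared goodness-of-fit statistic on aggregated frequencies
(n₁, n₂, n₃):

```
χ² = Σᵢ (nᵢ − n/3)² / (n/3),    n = n₁ + n₂ + n₃,    df = 2
```

Each gene tree contributes one unit vote split across the topologies in
proportion to its resolved quartets around *B* (so *n* is the effective
number of genes; gene trees with no resolved quartet around *B* are dropped,
and results with effective n < 10 are flagged as unreliable).  Failing to
reject never *proves* a polytomy — it may simply mean too little data; the
power analysis below quantifies that.

## Worked example

Simulate 200 true gene trees under the MSC on a quartet species tree whose
internal branch is 1 CU, then test that branch:

```sh
$ printf '((a:1,b:1):0.5,(c:1,d:1):0.5);\n' > quartet.nwk
$ quartetpoly simulate --species-tree quartet.nwk --genes 200 --seed 11 --out genes.nwk
$ quartetpoly test quartet.nwk genes.nwk
branch_id  clade  n1   n2  n3  effective_n  chi2    p_value      applicable  adjusted_p
0          c|d    146  28  26  200          141.64  1.75091e-31  true        NA
```

146 of 200 gene trees match the species tree (the MSC predicts
200·(1 − (2/3)e⁻¹) ≈ 151), the alternatives are near-equal as theory
requires, and the polytomy null is overwhelmingly rejected (p ≈ 2·10⁻³¹).
With a 0.2 CU branch instead, n₁ would shrink toward n/3 and hundreds of
genes would be needed; the closed-form power analysis gives the requirement
directly:

```sh
$ quartetpoly power -x 0.1
331
$ quartetpoly power -x 0.02
7641
```

i.e. rejecting a 0.1 CU branch at α = 0.05 takes at least 331 genes, and a
0.02 CU branch 7641 — the requirement grows as 1/x².

Other subcommands: `curve` (mean p-value vs subsampled gene count),
`experiment` (replicated simulation studies with per-branch rejection
rates), `collapse` (contract every non-rejected branch into a polytomy,
writing a multifurcating tree), and `--contract T` on `test` to first
collapse low-support gene-tree branches (support ≤ T).

The library mirrors the CLI: `test_branches`, `min_genes_to_reject`,
`simulate_gene_trees`, `yule_species_tree`, `s12_fixture`,
`run_rejection_experiment`, plus deviation models `skewed_probs` and
`gene_flow_probs` for exploring how skewed alternatives or gene flow move
quartet frequencies (gene flow can make a resolved branch look exactly like
a polytomy).

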