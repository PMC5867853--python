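# Methods

## Model and test

Under the multi-species coalescent (MSC), for four species whose unrooted
species tree is ab|cd with internal branch length *x* in coalescent units
(CU), the probability that a gene tree matches the species tree is
p₁ = 1 − (2/3)e^(−x); each alternative has p₂ = p₃ = (1/3)e^(−x).  With *n*
independent, error-free gene trees, the topology counts (n₁, n₂, n₃) are
multinomial.  A hard polytomy is the x = 0 boundary, where p₁ = p₂ = p₃ =
1/3; that equal-frequency hypothesis is tested per branch with the Pearson
statistic χ² = Σ(nᵢ − n/3)²/(n/3), asymptotically χ² with 2 df, whose
survival function for df = 2 is exactly e^(−χ²/2).

For trees with more than four taxa, a *quartet around a branch B* takes one
leaf from each of the four subtrees adjacent to B (the two child clades, the
sister clade, and the rest).  Under the locality assumption — every
positive-length branch of the given species tree, or an NNI neighbor of it,
is correct — each such quartet's internal branch equals B's, so all quartets
around B are informative about the same length.  The default aggregation
gives each gene tree one unit vote split proportionally to its resolved
quartet counts around B:

    f_{i,j} = n_{i,j} / Σᵢ n_{i,j},     nᵢ = Σⱼ f_{i,j}.

This handles missing taxa and unresolved (multifurcating) gene-tree quartets
by proportional imputation automatically; gene trees resolving no quartet
around B are discarded for B, so the *effective* gene count varies across
branches.  Counting each gene tree as a single observation, whatever the
number of quartets, is the most conservative treatment of the (unknown)
dependence between quartets; df stays at 2.  The liberal alternative (2m df
for m quartets) is deliberately not implemented.  Two alternative
aggregations, `single` (one fixed quartet) and `median` (componentwise
median of per-quartet counts), exist to check that the choice of aggregation
is not load-bearing; `mean` is the default.

The χ² approximation for three equiprobable cells is adequate from n ≥ 10;
branches with a smaller effective n get a reported p-value flagged
`applicable = false`, and downstream tree collapsing treats them as
non-rejections rather than aborting a whole-tree run.  Multiple-testing
corrections (Bonferroni, Benjamini–Hochberg) are available but off by
default: the test is normally screened over pre-selected branches, and the
reference analyses it follows did not correct either.

## Quartet counting

Naively there are |L||R||S||O| quartets around a branch.  The tally engine
never enumerates them: in any gene tree, a resolved quartet ab|cd is
witnessed at exactly the two endpoints of its internal path — the nodes at
which a and b lie in different components while c and d share a third
component.  Summing products of component-wise leaf counts (held as bitmask
popcounts) over all nodes and halving gives exact per-topology counts in
O(nodes) per gene tree and branch.  An explicit O(N⁴) enumerator lives in
the test suite and must agree to 1e-9; it is the oracle, never the
implementation.

## Power analysis

Setting the observed frequencies to their MSC expectations gives
E[χ²] = 2n(1 − e^(−x))², so the smallest rejecting gene count is
ceil(Q / (2(1 − e^(−x))²)) with Q the upper-α χ²₂ quantile (an upward scan
is kept as a test oracle, with integer-boundary guards on the ceiling).
For small x the requirement grows as 1/x²; the halving ratio
n(x/2)/n(x) = ((1−e^(−x))/(1−e^(−x/2)))² approaches 4 from below and is
within 2% of it for x ≲ 0.04.

Two deviation models describe how systematic departures from the MSC move
quartet frequencies: a skewed split of the alternative mass (p₂/p₃ = s,
default 1.2, i.e. 6/11 vs 5/11 of (2/3)e^(−x)), and an ILS + gene-flow
mixture for a network with a hybridization at the base,

    p1 = (1−λ)²(1 − (2/3)e^{−x}) + 2λ(1−λ)(1 − e^{−x/2} + (1/3)e^{−(x+4)})
       + λ²(1 − (2/3)e^{−x/2}),   p2 = p3 = (1 − p1)/2,

with λ the inheritance probability.  The printed source formula for the
middle term is typographically ambiguous; it is implemented with "/2"
halving the exponent (consistent with the λ² term) and "−4" as an additive
exponent constant encoding the fixed network branches, exposed as the
overridable `GENE_FLOW_EXPONENT_OFFSET`.  The λ = 0 and λ = 1 limits reduce
to the pure-MSC forms, and for λ ∈ (0, 1) there is a branch length at which
p₁ = 1/3 exactly — gene flow masquerading as a polytomy, which this test
cannot distinguish.

## Simulator

Gene trees are simulated directly in CU: within a species-tree branch
carrying k lineages, coalescence waits are Exp(k(k−1)/2); lineages surviving
to the root coalesce freely above it.  Zero-length branches are therefore
exact hard polytomies, and arbitrary binary resolutions with zero-length
edges are statistically identical to the multifurcating truth.  Only
topologies feed the test, so CU fully determines the relevant distribution;
generation/population-size parameters are converted at the boundary
(CU = generations / haploid population size) and never applied implicitly.
The simulator and the closed form p₁(x) are mutual oracles in the tests, and
an independent coalescent engine (msprime) is checked against the same law.

What the simulator emulates: true (error-free) gene trees, complete taxon
sampling, free recombination across loci.  What it does not: gene-tree
estimation error, missing data patterns of real datasets, gene flow,
duplication/loss.  Passing calibration tests therefore demonstrates the
statistical behavior of the test under its own assumptions, not robustness
on real data — where gene-tree error is known to inflate false positives
and shrink power.  A random-NNI perturbation surrogate for estimation error
is intentionally left out of the simulation studies shipped here.

## Study designs shipped with the package

* **12-taxon polytomy fixtures.**  Two ultrametric species trees of height
  8 CU (1.6 M generations at population size 2×10⁵).  Variant A has two
  3-child polytomies, a 0.2 CU focal branch (P0, parent of a polytomy) and a
  1 CU focal branch (P3, child of a polytomy); variant B has one 5-child
  polytomy and a 2 CU branch (P7) adjacent to it.  Branch lengths not pinned
  by those features are fixture constants chosen to keep every non-focal
  branch ≥ 1 CU so the focal branches dominate the local signal; focal-branch
  behavior under true gene trees is insensitive to them.
* **Yule power study.**  Pure-birth species trees, heights capped at
  500 K / 2 M / 10 M generations, speciation rates 10⁻⁶ and 10⁻⁷ per
  generation, population size 2×10⁵ (so caps are 2.5 / 10 / 50 CU).  When
  the natural crown height exceeds the cap, the whole tree is rescaled onto
  it — the slow-speciation settings thus sit exactly at the cap, mirroring
  designs that report trees *at* the stated heights.  This package scales the
  study down to 50-taxon trees with a handful of replicates per condition;
  per-branch rejection rates are pooled over conditions and, in
  `bin_rejection_by_length`, summarized in equisized log-length bins.
  Branch length for a root-spanning branch is the sum of the two rooted root
  edges (the unrooted length).

In the acceptance studies (`scripts/acceptance.py`) the type-I experiment
uses 50 replicates × 1000 genes on fixture A and reports the rejection rate
of the branch resolving the first 3-child polytomy; the power experiment
uses 5 replicates per Yule condition × 1000 genes and reports rejection
percentages among branches with true length in 0.1–0.2 CU and 0.05–0.15 CU.
These sizes keep the whole script at a few minutes on one core while
leaving dozens-to-hundreds of branches per bin.

## Numerical and design choices

* Branch identity is a canonical bipartition key: the side of the split not
  containing the alphabetically first taxon — stable under rerooting, and
  the key of every result map.
* Species trees are treated as unrooted for testing: a bifurcating root sits
  on a single unrooted branch (its two rooted edges are the same branch, and
  collapsing that branch contracts both), and the four sets around a
  root-incident branch are built from the sibling subtree's children.
* In the statistic, n = n₁ + n₂ + n₃ (not the raw gene count), which handles
  fractional tallies from partial resolution consistently; the all-zero
  tally is an error, and an effective n of zero yields a NaN-p, flagged row.
* Support-threshold contraction uses "at or below" semantics; edges without
  a support value are never contracted (absence of evidence is not low
  support).  Support scale (percent vs fraction) is auto-detectable but the
  threshold is compared on the tree's own scale.
* Arbitrary polytomy resolution introduces zero-length edges only, refines
  the input (all input bipartitions preserved) and is deterministic per
  seed.  Simulation seeds derive from a single master seed via
  `numpy.random.SeedSequence` spawning; fixed seeds reproduce byte-identical
  newick output.
* Reported p-values are floored at 1e-300 in CLI output and flagged, so
  output never depends on platform underflow behavior.

## Limitations

The test inherits the locality assumption (a wrong species-tree resolution
elsewhere can bias quartet sets), treats gene trees as error-free samples,
and has no optimal-power guarantee — likelihood-ratio approaches can be more
powerful.  Retaining the null is never evidence *for* a polytomy: the
required gene counts above show how quickly power evaporates below ~0.03 CU.
Exact multinomial testing for effective n < 10 and local posterior
probabilities are out of scope.
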