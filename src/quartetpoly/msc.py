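"""Closed-form multi-species-coalescent quartet math and power analysis.

For a quartet species tree whose internal branch has length x in coalescent
units (CU = generations / haploid population size), a gene tree matches the
species-tree topology with probability

    p1 = 1 - (2/3) e^{-x},        p2 = p3 = (1/3) e^{-x},

the two alternatives being equally likely.  At x = 0 all three topologies are
equifrequent, which is the polytomy null the chi-squared test targets.  From
these probabilities follow the expected test statistic at a given gene count,
the minimum number of genes needed to reject a branch of a given length, and
two deviation models: a skewed split of the alternative mass, and quartet
frequencies under combined incomplete lineage sorting and gene flow.
"""

from __future__ import annotations

import math

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "quartet_probs",
    "hoeffding_bound",
    "expected_chi2",
    "min_genes_to_reject",
    "skewed_probs",
    "gene_flow_probs",
    "cu_from_generations",
    "generations_from_cu",
    "GENE_FLOW_EXPONENT_OFFSET",
]

#: additive constant in the exponent of the middle gene-flow term; it encodes
#: the fixed internal branches of the hybridization network this deviation
#: model was derived for, and can be overridden by callers needing another
#: network geometry.
GENE_FLOW_EXPONENT_OFFSET = 4.0


def quartet_probs(x: float) -> tuple[float, float, float]:
    """MSC probabilities (p1, p2, p3) of the three quartet topologies."""
    if x < 0:
        raise ValueError("branch length in coalescent units must be >= 0")
    e = math.exp(-x)
    return (1.0 - 2.0 * e / 3.0, e / 3.0, e / 3.0)


def hoeffding_bound(epsilon: float, n: int) -> float:
    """Upper bound 2·exp(-2·eps²·n) on P(|n1/n - p1| >= eps), capped at 1."""
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return min(1.0, 2.0 * math.exp(-2.0 * epsilon * epsilon * n))


def expected_chi2(x: float, n: float) -> float:
    """Test statistic when observed frequencies equal MSC expectations.

    Plugging n_i = n·p_i(x) into the statistic gives 3n·sum (p_i - 1/3)^2,
    which simplifies to 2n(1 - e^{-x})^2.
    """
    if x < 0:
        raise ValueError("branch length must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * n * (1.0 - math.exp(-x)) ** 2


def min_genes_to_reject(x: float, alpha: float = 0.05) -> int:
    """Smallest gene count whose expected statistic rejects at level alpha.

    Closed form: ceil(Q / (2(1-e^{-x})^2)) with Q the upper-alpha quantile of
    chi-squared(df=2).  A zero-length branch can never be rejected.
    """
    if x <= 0:
        raise ValueError("a zero-length branch is never rejectable")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = float(_chi2_dist.isf(alpha, df=2))
    per_gene = 2.0 * (1.0 - math.exp(-x)) ** 2
    n = math.ceil(q / per_gene)
    # guard the ceiling against floating error at exact-integer boundaries
    while expected_chi2(x, n) < q:
        n += 1
    while n > 1 and expected_chi2(x, n - 1) >= q:
        n -= 1
    return n


def skewed_probs(x: float, skew: float = 1.2) -> tuple[float, float, float]:
    """Deviation model: the alternative mass (2/3)e^{-x} split in ratio skew:1.

    ``skew = p2/p3``; 1.2 gives the 6/11 vs 5/11 split, and 1 recovers the
    plain MSC probabilities.
    """
    if x < 0:
        raise ValueError("branch length must be >= 0")
    if skew <= 0:
        raise ValueError("skew must be positive")
    e = math.exp(-x)
    alt = 2.0 * e / 3.0
    p3 = alt / (1.0 + skew)
    return (1.0 - alt, skew * p3, p3)


def gene_flow_probs(
    x: float,
    lam: float,
    exponent_offset: float = GENE_FLOW_EXPONENT_OFFSET,
) -> tuple[float, float, float]:
    """Quartet frequencies under combined ILS and gene flow.

    ``lam`` is the inheritance probability of the gene-flow edge in a
    hybridization network with the flow at the base; the three mixture terms
    weight the no-flow, one-sided and two-sided inheritance histories:

        p1 = (1-lam)^2 (1 - (2/3)e^{-x})
           + 2 lam (1-lam) (1 - e^{-x/2} + (1/3) e^{-(x + offset)})
           + lam^2 (1 - (2/3) e^{-x/2})

    with p2 = p3 = (1 - p1)/2.  ``lam = 0`` recovers the MSC probabilities.
    """
    if x < 0:
        raise ValueError("branch length must be >= 0")
    if not 0 <= lam <= 1:
        raise ValueError("inheritance probability must be in [0, 1]")
    p1 = (
        (1 - lam) ** 2 * (1.0 - 2.0 / 3.0 * math.exp(-x))
        + 2 * lam * (1 - lam)
        * (1.0 - math.exp(-x / 2.0) + math.exp(-(x + exponent_offset)) / 3.0)
        + lam ** 2 * (1.0 - 2.0 / 3.0 * math.exp(-x / 2.0))
    )
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"mis-parameterized model: p1 = {p1!r} outside [0, 1]")
    p23 = (1.0 - p1) / 2.0
    return (p1, p23, p23)


def cu_from_generations(generations: float, pop_size: float) -> float:
    """Convert a branch length in generations to coalescent units."""
    if pop_size <= 0:
        raise ValueError("population size must be positive")
    return generations / pop_size


def generations_from_cu(cu: float, pop_size: float) -> float:
    if pop_size <= 0:
        raise ValueError("population size must be positive")
    return cu * pop_size
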