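"""Chi-squared polytomy test on per-branch quartet tallies.

Null hypothesis for a branch B: the three quartet topologies around B are
equifrequent among gene trees (what a zero-length branch -- a polytomy --
implies under the multi-species coalescent).  The statistic

    chi2 = sum_i (n_i - n/3)^2 / (n/3),      n = n1 + n2 + n3

is asymptotically chi-squared with 2 degrees of freedom, an approximation we
trust only for an effective gene count >= 10; below that the result is
reported but flagged not applicable.  Each gene tree counts as a single
observation no matter how many quartets surround the branch -- the most
conservative treatment of quartet dependence -- so df stays at 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
from scipy.stats import chi2 as _chi2_dist

from .quartets import QuartetTally, all_branch_tallies

__all__ = [
    "MIN_EFFECTIVE_N",
    "PolytomyTestResult",
    "chi2_statistic",
    "polytomy_pvalue",
    "test_tally",
    "test_branches",
]

#: assumption on the chi-squared approximation: effective n below this is flagged
MIN_EFFECTIVE_N = 10

Correction = Literal["none", "bonferroni", "bh"]


@dataclass
class PolytomyTestResult:
    """Outcome of the polytomy test for one branch (df fixed at 2)."""

    chi2: float
    p_value: float
    effective_n: int
    n1: float
    n2: float
    n3: float
    applicable: bool
    adjusted_p: float | None = None
    df: int = 2


def chi2_statistic(tally: QuartetTally | Sequence[float]) -> float:
    """Goodness-of-fit statistic against equal expected frequencies n/3.

    Accepts a :class:`QuartetTally` or a plain (n1, n2, n3) triple; fractional
    counts (from the mean aggregation with missing data) are fine.
    """
    if isinstance(tally, QuartetTally):
        n1, n2, n3 = tally.n1, tally.n2, tally.n3
    else:
        n1, n2, n3 = tally
    n = n1 + n2 + n3
    if n <= 0:
        raise ValueError("cannot test an all-zero tally")
    e = n / 3.0
    return ((n1 - e) ** 2 + (n2 - e) ** 2 + (n3 - e) ** 2) / e


def polytomy_pvalue(chi2: float) -> float:
    """Right-tail area of the chi-squared(df=2) distribution at ``chi2``.

    For df=2 this equals exp(-chi2/2) exactly; the survival function is used
    so the statistic's distribution is stated once, in scipy's terms.
    """
    if chi2 < 0:
        raise ValueError("chi-squared statistic cannot be negative")
    return float(_chi2_dist.sf(chi2, df=2))


def test_tally(tally: QuartetTally) -> PolytomyTestResult:
    """Run the test on one branch tally."""
    stat = chi2_statistic(tally)
    return PolytomyTestResult(
        chi2=stat,
        p_value=polytomy_pvalue(stat),
        effective_n=tally.effective_n,
        n1=tally.n1,
        n2=tally.n2,
        n3=tally.n3,
        applicable=tally.effective_n >= MIN_EFFECTIVE_N,
    )


_CORRECTION_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def _adjust(results: Mapping[frozenset, PolytomyTestResult], correction: Correction) -> None:
    if correction not in _CORRECTION_METHODS:
        raise ValueError(f"unknown correction {correction!r}")
    keys = [k for k, r in results.items() if r.applicable]
    if not keys:
        return
    from statsmodels.stats.multitest import multipletests

    ps = [results[k].p_value for k in keys]
    _, adj, _, _ = multipletests(ps, method=_CORRECTION_METHODS[correction])
    for k, a in zip(keys, adj):
        results[k].adjusted_p = float(a)


def test_branches(
    species_tree: dendropy.Tree,
    genes: Sequence[dendropy.Tree],
    alpha: float = 0.05,
    correction: Correction = "none",
    method: str = "mean",
) -> dict[frozenset, PolytomyTestResult]:
    """Test every internal branch of the species tree independently.

    Returns a map from canonical clade (the branch's bipartition side not
    containing the alphabetically first taxon) to the per-branch result.
    Branches with effective n below :data:`MIN_EFFECTIVE_N` are reported but
    flagged; with a correction requested, adjusted p-values are computed
    across the applicable branches only.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tallies = all_branch_tallies(species_tree, genes, method=method)
    results: dict[frozenset, PolytomyTestResult] = {}
    for key, tally in tallies.items():
        if tally.effective_n == 0:
            results[key] = PolytomyTestResult(
                chi2=math.nan, p_value=math.nan, effective_n=0,
                n1=0.0, n2=0.0, n3=0.0, applicable=False,
            )
            continue
        results[key] = test_tally(tally)
    if correction != "none":
        _adjust(results, correction)
    return results
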