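"""Mendelian segregation models for bulked-segregant designs.

A selfed heterozygous parent segregates 1 MM : 2 Mm : 1 mm, so a recessive
mutant phenotype appears in 1/4 of progeny (the classic 3:1 ratio) and 2/3 of
the phenotypically wildtype progeny are carriers. From the bulk composition we
can therefore predict the mutant-allele read fraction expected in each pool,
and test observed allele depths against that expectation with an exact
binomial test. This predicted ratio is what separates the causal variant from
background mutations that merely differ between the bulks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy import stats

DEFAULT_ERROR_RATE = 0.01


@dataclass(frozen=True)
class BulkDesign:
    """Composition of one sequenced pool under a stated inheritance model.

    ``het_count`` is the number of heterozygous plants in a wildtype-phenotype
    bulk when known from genotyping; leave ``None`` to fall back on the 2/3
    carrier expectation of a 3:1 selfed family. Mutant-role bulks contain only
    homozygous mutant plants under monogenic recessive inheritance.
    """

    role: Literal["mutant", "wildtype"]
    n_plants: int
    het_count: int | None = None
    inheritance: str = "monogenic_recessive"
    family: str = "selfed_het_parent"

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("n_plants must be positive")
        if self.inheritance != "monogenic_recessive":
            raise NotImplementedError(self.inheritance)
        if self.het_count is not None:
            if self.role == "mutant":
                raise ValueError(
                    "het_count is meaningless for a mutant bulk: recessive "
                    "homozygotes only"
                )
            if not 0 <= self.het_count <= self.n_plants:
                raise ValueError("het_count outside [0, n_plants]")


@dataclass(frozen=True)
class SegregationCounts:
    """Observed phenotype counts against an expected ratio (wt:mut)."""

    n_mutant: int
    n_wildtype: int
    expected_ratio: tuple[float, float] = (3, 1)  # (wt_parts, mut_parts)

    def __post_init__(self) -> None:
        if self.n_mutant < 0 or self.n_wildtype < 0:
            raise ValueError("counts must be non-negative")
        if min(self.expected_ratio) <= 0:
            raise ValueError("ratio parts must be positive")


def expected_alt_fraction(design: BulkDesign) -> float:
    """Predicted mutant-allele read fraction of a pool.

    Each plant contributes equally to the pool, and each heterozygote
    contributes the mutant allele at half dose:

    * mutant bulk: all plants mm -> 1.0
    * wildtype bulk, ``h`` of ``n`` plants known heterozygous -> h / (2n)
    * wildtype bulk, composition unknown but drawn from a 3:1 selfed family:
      2/3 of phenotypic wildtypes carry one mutant allele -> (2/3)(1/2) = 1/3
    """
    if design.role == "mutant":
        return 1.0
    if design.het_count is not None:
        return design.het_count / (2 * design.n_plants)
    return 1.0 / 3.0


def chisq_segregation(
    counts: SegregationCounts, continuity_correction: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square goodness of fit of phenotype counts to a ratio.

    Returns ``(chi2, p_value, df)`` with df fixed at 1 (two phenotype
    classes). No Yates continuity correction by default; pass
    ``continuity_correction=True`` for the corrected statistic.
    """
    n = counts.n_mutant + counts.n_wildtype
    if n == 0:
        raise ValueError("no observations")
    wt_parts, mut_parts = counts.expected_ratio
    total_parts = wt_parts + mut_parts
    e_mut = n * mut_parts / total_parts
    e_wt = n * wt_parts / total_parts
    if e_mut == 0 or e_wt == 0:
        raise ValueError("zero expected count")
    chi2 = 0.0
    for obs, exp in ((counts.n_mutant, e_mut), (counts.n_wildtype, e_wt)):
        dev = abs(obs - exp)
        if continuity_correction:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / exp
    df = 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p, df


def binomial_consistency(
    ad_alt: int,
    depth_used: int,
    f_expected: float,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> float:
    """Exact two-sided binomial p-value for observed alt reads vs expectation.

    The expected fraction is clamped to ``[error_rate, 1 - error_rate]`` so a
    nominal expectation of 0 or 1 still tolerates sequencing-error reads. The
    two-sided p sums the probabilities of all outcomes no more likely than the
    observation (minimum-likelihood definition, well-defined for asymmetric
    expectations). Zero depth carries no evidence and returns 1.
    """
    if not 0 <= ad_alt <= depth_used:
        raise ValueError("need 0 <= ad_alt <= depth_used")
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    if depth_used == 0:
        return 1.0
    f = min(max(f_expected, error_rate), 1.0 - error_rate)
    return float(stats.binomtest(ad_alt, depth_used, f).pvalue)
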