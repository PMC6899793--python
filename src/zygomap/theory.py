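"""Quantitative framework for zygosity mapping vs bulked segregant analysis.

All quantities are closed-form and interference-free.  Resolution values are
returned at full precision; round only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .zygosity import ZygosityPattern, FULL_SET

#: Genotype prior at a SNP that was heterozygous in the selfed M1:
#: P(hom_wt, het, hom_mut) = (1/4, 1/2, 1/4).
SELFED_HET_PRIOR = (0.25, 0.5, 0.25)


@dataclass
class TheoryParams:
    """Design parameters of a mapping experiment."""

    alpha: float = 0.05
    m: int = 32                      # number of meiotic events (2 per selfed diploid)
    map_length_cM: float = 2200.0    # total genetic map length
    n_snps: int = 1357               # segregating induced SNPs
    n_individuals: int = 16
    coverage_per_individual: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.m < 1:
            raise ValidationError(f"need at least one meiosis, got m={self.m}")
        if self.map_length_cM <= 0:
            raise ValidationError("map length must be positive")


def unlinked_match_probability(
    pattern: ZygosityPattern,
    prior: tuple[float, float, float] = SELFED_HET_PRIOR,
) -> float:
    """Probability that an unlinked segregating SNP matches the pattern.

    Under independent 1:2:1 segregation the chance is the product, over
    constrained individuals, of the prior mass of each allowed set: a
    singleton homozygous class contributes 1/4, {het} contributes 1/2 and
    {het, hom_wt} contributes 3/4.  A fully determined pattern of 16
    homozygous-constrained individuals gives 0.25^16 ~ 2.33e-10.
    """
    p = 1.0
    for iid in pattern.ids:
        allowed = pattern.allowed[iid]
        if not allowed:
            raise ValidationError(f"empty allowed set for {iid!r}")
        if allowed == FULL_SET:
            continue
        p *= sum(prior[d] for d in allowed)
    return p


def bsa_resolution_cm(alpha: float, m: int) -> float:
    """Mapping resolution of bulked segregant analysis in cM.

    The genetic interval around the causal locus within which fewer than a
    fraction ``alpha`` of ``m`` meioses are expected to recombine:
    ``100 * (1 - alpha**(1/m))``.
    """
    if m < 1:
        raise ValidationError(f"need at least one meiosis, got m={m}")
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must lie in (0,1], got {alpha}")
    return 100.0 * (1.0 - alpha ** (1.0 / m))


def meiotic_resolution_cm(m: int) -> tuple[float, float]:
    """Mean resolution of zygosity mapping and the unresolved region around
    the causal locus, both in cM.

    With ``m`` meioses the expected distance to the nearest informative
    crossover is 100/m cM per side, so the unresolved block spans twice that.
    """
    if m < 1:
        raise ValidationError(f"need at least one meiosis, got m={m}")
    resolution = 100.0 / m
    return resolution, 2.0 * resolution


def expected_linked_snp_count(n_snps: int, region_cM: float, map_length_cM: float) -> float:
    """Expected number of induced SNPs inside a linkage region, assuming
    uniform placement on the genetic map."""
    if map_length_cM <= 0:
        raise ValidationError("map length must be positive")
    if region_cM > map_length_cM:
        raise ValidationError("region cannot exceed the map length")
    return n_snps * region_cM / map_length_cM


def coverage_comparison(
    n_individuals: int = 16,
    coverage_per_individual: float = 20.0,
    bsa_pool_size: int = 50,
    per_allele_factor: float = 1.0,
    recommended_factors: tuple[float, float] = (2.0, 3.0),
) -> dict[str, float]:
    """Total sequencing requirements: individual zygosity mapping vs BSA.

    Zygosity mapping needs ``n_individuals * coverage_per_individual`` fold
    coverage in total; a BSA pool of ``2 * pool_size`` alleles needs at
    minimum one read per allele and in practice 2-3x per allele to resolve
    allele frequencies.
    """
    if n_individuals < 0 or bsa_pool_size < 0:
        raise ValidationError("counts must be non-negative")
    zygosity_total = n_individuals * coverage_per_individual
    n_alleles = 2 * bsa_pool_size
    bsa_minimal = n_alleles * per_allele_factor
    bsa_low, bsa_high = (n_alleles * f for f in recommended_factors)
    return {
        "zygosity_total_x": zygosity_total,
        "bsa_minimal_x": bsa_minimal,
        "bsa_recommended_low_x": bsa_low,
        "bsa_recommended_high_x": bsa_high,
        "efficiency_vs_minimal": zygosity_total / bsa_minimal if bsa_minimal else float("inf"),
        "efficiency_vs_recommended_low": zygosity_total / bsa_low if bsa_low else float("inf"),
        "efficiency_vs_recommended_high": zygosity_total / bsa_high if bsa_high else float("inf"),
    }


def monte_carlo_match_rate(
    pattern: ZygosityPattern,
    n_draws: int,
    rng: np.random.Generator,
    prior: tuple[float, float, float] = SELFED_HET_PRIOR,
) -> tuple[float, float]:
    """Empirical match rate of independently drawn 1:2:1 genotype vectors.

    Returns (rate, Monte-Carlo standard error).  Serves as the stochastic
    cross-check of :func:`unlinked_match_probability`.
    """
    constrained = [pattern.allowed[i] for i in pattern.ids if pattern.allowed[i] != FULL_SET]
    if not constrained:
        return 1.0, 0.0
    draws = rng.choice(3, size=(n_draws, len(constrained)), p=list(prior))
    ok = np.ones(n_draws, dtype=bool)
    for j, allowed in enumerate(constrained):
        allowed_arr = np.zeros(3, dtype=bool)
        for d in allowed:
            allowed_arr[d] = True
        ok &= allowed_arr[draws[:, j]]
    rate = ok.mean()
    se = float(np.sqrt(max(rate * (1 - rate), 1.0 / n_draws) / n_draws))
    return float(rate), se
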