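"""Mutation-rate estimation from fluctuation-assay colony counts.

A fluctuation test grows many parallel cultures from small inocula, plates
dilutions on selective and permissive media, and infers the per-cell-division
mutation rate from the distribution of mutant counts.  Because mutations
arising early in a culture produce "jackpot" clones, the mean mutant
frequency is a poor estimator; Drake's median-based formula

    mu = f / ln(N * mu)

with ``f`` the median mutant frequency and ``N`` the population size, is the
classical robust alternative.  The equation is implicit in ``mu`` and is
solved numerically here.

Apparent resistant colonies that pass phenotype verification (e.g. FOA-
resistant colonies that are still Ura+ because the reporter is epigenetically
silenced rather than mutated) are excluded from every calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

__all__ = [
    "Culture",
    "CultureSet",
    "RateEstimate",
    "SynergyResult",
    "corrected_mutant_counts",
    "population_sizes",
    "median_mutant_frequency",
    "drake_rate",
    "rate_confidence_interval",
    "estimate_rate",
    "fold_change",
    "synergy_index",
]


@dataclass(frozen=True)
class Culture:
    """Plate counts for one culture of a fluctuation assay.

    Dilution factors are the fold-dilution applied before plating, so the
    per-culture census is ``count * dilution``.
    """

    selective_count: int
    selective_dilution: float
    permissive_count: int
    permissive_dilution: float
    verified_silenced_count: int = 0

    def __post_init__(self) -> None:
        if self.selective_count < 0 or self.permissive_count < 0:
            raise ValueError("colony counts must be non-negative")
        if self.verified_silenced_count < 0:
            raise ValueError("verified_silenced_count must be non-negative")
        if self.selective_dilution <= 0 or self.permissive_dilution <= 0:
            raise ValueError("dilution factors must be positive")
        if self.verified_silenced_count > self.selective_count:
            raise ValueError(
                "verified_silenced_count exceeds selective_count"
            )


@dataclass
class CultureSet:
    """All cultures of one genotype/locus fluctuation experiment."""

    genotype: str
    locus: str
    cultures: list[Culture] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cultures)


@dataclass
class RateEstimate:
    """A mutation rate per cell division with its provenance.

    ``is_upper_bound`` marks the zero-mutant convention: when the median
    mutant frequency is zero the reported rate is the bound obtained from a
    single hypothetical mutant (f_min = 1/N).
    """

    mu: float
    ci_low: float
    ci_high: float
    f_median: float
    n_population: float
    n_cultures: int
    is_upper_bound: bool = False
    ci_flagged: bool = False


@dataclass(frozen=True)
class SynergyResult:
    """Epistasis summary: relative double-mutant rate vs the additive sum."""

    rel_a: float
    rel_b: float
    rel_ab: float
    index: float


def corrected_mutant_counts(cs: CultureSet) -> np.ndarray:
    """Per-culture mutant census after excluding verified silenced colonies.

    corrected = (selective_count - verified_silenced_count) * selective_dilution
    """
    out = np.array(
        [
            (c.selective_count - c.verified_silenced_count)
            * c.selective_dilution
            for c in cs.cultures
        ],
        dtype=float,
    )
    if (out < 0).any():
        raise ValueError("negative corrected mutant count (corrupt data)")
    return out


def population_sizes(cs: CultureSet) -> np.ndarray:
    """Per-culture total-cell census from the permissive plates."""
    return np.array(
        [c.permissive_count * c.permissive_dilution for c in cs.cultures],
        dtype=float,
    )


def median_mutant_frequency(
    corrected_counts: Sequence[float], pop_sizes: Sequence[float]
) -> float:
    """Median over cultures of mutant census / population census.

    Even-length medians are the mean of the two central order statistics.
    """
    counts = np.asarray(corrected_counts, dtype=float)
    pops = np.asarray(pop_sizes, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one culture")
    if counts.shape != pops.shape:
        raise ValueError("counts and population sizes differ in length")
    if (pops <= 0).any():
        raise ValueError("population census must be positive in every culture")
    return float(np.median(counts / pops))


def drake_rate(f: float, n_population: float, rtol: float = 1e-10) -> float:
    """Solve mu * ln(N * mu) = f for the mutation rate mu.

    The root is unique on (e/N, f]: the left-hand side is strictly
    increasing there, equals e/N < f at the left end and f*ln(N*f) >= f at
    the right end whenever N > e/f.  Solved by Brent's method to relative
    tolerance ``rtol``.

    Raises ``ValueError`` when f <= 0 or when no bracket exists
    (N <= e/f, i.e. fewer than ~e expected mutants per culture).
    """
    if f <= 0:
        raise ValueError("median mutant frequency must be positive "
                         "(zero-mutant data only supports an upper bound)")
    if n_population <= math.e / f:
        raise ValueError(
            "no root with N*mu > e exists: population too small for the "
            "observed frequency"
        )
    lo = math.e / n_population * (1 + 1e-12)
    hi = f
    mu = brentq(
        lambda m: m * math.log(n_population * m) - f,
        lo, hi, rtol=4 * np.finfo(float).eps, xtol=1e-300,
    )
    # Newton polish: drives the residual to machine precision so the
    # contract |mu*ln(N*mu) - f| <= rtol*f holds with margin
    for _ in range(3):
        resid = mu * math.log(n_population * mu) - f
        if abs(resid) <= rtol * f / 10:
            break
        mu -= resid / (math.log(n_population * mu) + 1)
    return float(mu)


def _drake_rate_clamped(f: float, n_population: float) -> float:
    """drake_rate with graceful handling of frequencies at/below the bracket.

    Used for confidence bounds: a bound frequency of 0 maps to rate 0, and a
    tiny positive frequency below e/N (where the implicit equation has no
    root) maps to the limiting value f (since mu -> f as ln(N*mu) -> 1).
    """
    if f <= 0:
        return 0.0
    if n_population <= math.e / f:
        return min(f, math.e / n_population)
    return drake_rate(f, n_population)


def _median_ci_ranks(n: int, level: float) -> tuple[int, int, bool]:
    """Symmetric order-statistic ranks (1-based) covering the median.

    Returns (lo, hi, flagged): the largest symmetric pair with coverage
    >= level, or the widest available pair (1, n) flagged when even that
    does not reach the level.
    """
    # coverage of (k, n+1-k) is 1 - 2*P(X <= k-1), X ~ Binom(n, 1/2)
    best = None
    for k in range(n // 2, 0, -1):
        cover = 1 - 2 * binom.cdf(k - 1, n, 0.5)
        if cover >= level:
            best = k
            break
    if best is None:
        return 1, n, True
    return best, n + 1 - best, False


def rate_confidence_interval(
    cs: CultureSet, level: float = 0.95
) -> tuple[float, float, bool]:
    """Distribution-free CI on the mutation rate.

    Binomial order statistics give a nonparametric CI on the median mutant
    frequency; each bound is then mapped through the Drake solve with the
    same population size N, which is monotone, so the interval transfers.

    Returns (ci_low, ci_high, flagged); flagged means too few cultures to
    reach the nominal level and the widest available bounds were used.
    """
    n = len(cs)
    if n < 1:
        raise ValueError("empty culture set")
    counts = corrected_mutant_counts(cs)
    pops = population_sizes(cs)
    freqs = np.sort(counts / pops)
    n_pop = float(np.median(pops))
    lo_rank, hi_rank, flagged = _median_ci_ranks(n, level)
    f_lo = float(freqs[lo_rank - 1])
    f_hi = float(freqs[hi_rank - 1])
    return (
        _drake_rate_clamped(f_lo, n_pop),
        _drake_rate_clamped(f_hi, n_pop),
        flagged,
    )


def estimate_rate(
    cs: CultureSet, level: float = 0.95, n_summary: str = "median"
) -> RateEstimate:
    """Full Drake pipeline: exclusion, median frequency, solve, CI.

    ``n_summary`` selects how the per-culture population censuses are
    collapsed into the single N of the formula ("median" or "mean").

    When the median mutant frequency is zero the returned rate is the upper
    bound from one hypothetical mutant (f_min = 1/N) and ``is_upper_bound``
    is set.
    """
    if len(cs) < 1:
        raise ValueError("empty culture set")
    counts = corrected_mutant_counts(cs)
    pops = population_sizes(cs)
    f = median_mutant_frequency(counts, pops)
    if n_summary == "median":
        n_pop = float(np.median(pops))
    elif n_summary == "mean":
        n_pop = float(np.mean(pops))
    else:
        raise ValueError("n_summary must be 'median' or 'mean'")
    if f > 0:
        mu = drake_rate(f, n_pop)
        upper = False
    else:
        mu = _drake_rate_clamped(1.0 / n_pop, n_pop)
        upper = True
    ci_low, ci_high, flagged = rate_confidence_interval(cs, level)
    # numerical safety: the point estimate sits between the transformed bounds
    ci_low = min(ci_low, mu)
    ci_high = max(ci_high, mu)
    return RateEstimate(
        mu=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        f_median=f,
        n_population=n_pop,
        n_cultures=len(cs),
        is_upper_bound=upper,
        ci_flagged=flagged,
    )


def fold_change(mu_mutant: float, mu_reference: float) -> float:
    """Ratio of two mutation rates (mutant over reference)."""
    if mu_reference <= 0:
        raise ValueError("reference rate must be positive")
    return mu_mutant / mu_reference


def synergy_index(
    mu_wt: float, mu_a: float, mu_b: float, mu_ab: float
) -> SynergyResult:
    """Epistasis index: relative double-mutant rate over the additive sum.

    index = (mu_ab/mu_wt) / (mu_a/mu_wt + mu_b/mu_wt); values > 1 indicate
    super-additivity, i.e. the two gene products act on overlapping pools of
    replication errors.
    """
    if min(mu_wt, mu_a, mu_b, mu_ab) <= 0:
        raise ValueError("all rates must be positive")
    rel_a = mu_a / mu_wt
    rel_b = mu_b / mu_wt
    rel_ab = mu_ab / mu_wt
    return SynergyResult(
        rel_a=rel_a, rel_b=rel_b, rel_ab=rel_ab,
        index=rel_ab / (rel_a + rel_b),
    )
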