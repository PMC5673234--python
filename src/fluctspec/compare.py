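"""Statistical comparison of mutation spectra between genotypes.

Two procedures are provided.  The asymptotic route tests independence of
mutation category and genotype with Pearson's chi-square (no continuity
correction, chi-square reference distribution even at small expected counts
— the convention used when spectra of ~50 mutations are compared) and
adjusts the family of pairwise p-values with the Bonferroni correction.

The Monte-Carlo route assesses the same Pearson statistic against its exact
conditional null: tables with both margins fixed, equivalent to randomly
permuting the genotype label of each individual mutation, sampled with
Patefield's algorithm.  It reports the add-one permutation p-value and the
empirical 5% critical value of the null distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import format_p
from .spectrum import MutationSpectrum

__all__ = [
    "ContingencyTable",
    "ChiSqResult",
    "MonteCarloResult",
    "chisq_independence",
    "bonferroni",
    "mc_homogeneity",
    "pairwise_compare",
    "spectra_to_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Category-by-genotype count table."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(
            counts=tuple(tuple(int(x) for x in row) for row in df.to_numpy()),
            row_labels=tuple(str(r) for r in df.index),
            col_labels=tuple(str(c) for c in df.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.counts), index=list(self.row_labels),
            columns=list(self.col_labels),
        )

    def __post_init__(self) -> None:
        arr = np.array(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    def drop_zero_margins(self) -> "ContingencyTable":
        """Remove all-zero rows and columns (they carry no information)."""
        arr = np.array(self.counts)
        rkeep = arr.sum(axis=1) > 0
        ckeep = arr.sum(axis=0) > 0
        sub = arr[np.ix_(rkeep, ckeep)]
        return ContingencyTable(
            counts=tuple(tuple(int(x) for x in row) for row in sub),
            row_labels=tuple(l for l, k in zip(self.row_labels, rkeep) if k),
            col_labels=tuple(l for l, k in zip(self.col_labels, ckeep) if k),
        )


@dataclass(frozen=True)
class ChiSqResult:
    """Asymptotic chi-square test result with Bonferroni adjustment."""

    comparison: str
    statistic: float
    df: int
    p: float
    p_adjusted: float | None = None
    m: int | None = None
    small_expected: bool = False

    @property
    def p_text(self) -> str:
        return format_p(self.p)


@dataclass(frozen=True)
class MonteCarloResult:
    """Fixed-margin Monte-Carlo homogeneity test result."""

    comparison: str
    statistic_observed: float
    p_mc: float
    critical_value_5pct: float
    n_iter: int
    seed: int
    n_exceed: int = 0

    @property
    def p_text(self) -> str:
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.p_mc:.4g}"


def _pearson_statistic(observed: np.ndarray) -> tuple[float, np.ndarray]:
    """Pearson chi-square statistic and the expected table (margins fixed)."""
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, expected


def chisq_independence(table: ContingencyTable) -> ChiSqResult:
    """Pearson chi-square test of independence on a category-genotype table.

    Zero-margin rows/columns are dropped before computing df =
    (rows-1)(cols-1).  The asymptotic chi-square p is used regardless of
    small expected counts (a warning notes when any expected cell is < 5).
    """
    reduced = table.drop_zero_margins()
    arr = np.array(reduced.counts, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("degenerate table after dropping zero margins")
    res = stats.chi2_contingency(arr, correction=False)
    small = bool((res.expected_freq < 5).any())
    if small:
        warnings.warn(
            "expected counts below 5; asymptotic chi-square p is approximate"
        )
    return ChiSqResult(
        comparison=" vs ".join(reduced.col_labels),
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        small_expected=small,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m * p) for a family of m comparisons."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def mc_homogeneity(
    table: ContingencyTable, n_iter: int = 100_000, seed: int = 0
) -> MonteCarloResult:
    """Monte-Carlo Pearson chi-square test of spectra homogeneity.

    Null tables preserve both margins — each individual mutation keeps its
    category but is randomly reassigned a genotype column — sampled from
    the conditional (multivariate hypergeometric) distribution.  The
    add-one estimator p = (1 + #{sim >= obs}) / (1 + n_iter) keeps p > 0;
    when no simulated statistic reaches the observed one the result prints
    as "< 1/n_iter".
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    reduced = table.drop_zero_margins()
    arr = np.array(reduced.counts, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("degenerate table after dropping zero margins")
    if (np.array(table.counts).sum(axis=0) == 0).any():
        raise ValueError("zero column total")
    observed_stat, expected = _pearson_statistic(arr)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(arr.sum(axis=1), arr.sum(axis=0))
    sims = sampler.rvs(n_iter, random_state=rng)  # (n_iter, r, c)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    n_exceed = int((sim_stats >= observed_stat - 1e-12).sum())
    p_mc = (1 + n_exceed) / (1 + n_iter)
    return MonteCarloResult(
        comparison=" vs ".join(reduced.col_labels),
        statistic_observed=observed_stat,
        p_mc=float(p_mc),
        critical_value_5pct=float(np.percentile(sim_stats, 95)),
        n_iter=n_iter,
        seed=seed,
        n_exceed=n_exceed,
    )


def spectra_to_table(spectra: Sequence[MutationSpectrum]) -> ContingencyTable:
    """Stack spectra into a category-by-genotype contingency table."""
    cats = list(spectra[0].counts)
    for s in spectra[1:]:
        if list(s.counts) != cats:
            raise ValueError("spectra have different category sets")
    df = pd.DataFrame(
        {s.genotype: [s.counts[c] for c in cats] for s in spectra},
        index=cats,
    )
    return ContingencyTable.from_frame(df)


def pairwise_compare(
    spectra: Sequence[MutationSpectrum],
    method: str = "chisq",
    n_iter: int = 100_000,
    seed: int = 0,
    p_decimals: int = 4,
) -> list[ChiSqResult] | list[MonteCarloResult]:
    """All pairwise spectrum comparisons, plus the overall test for chisq.

    For the asymptotic method the Bonferroni family size m counts every
    reported comparison including the overall all-genotypes test (m = 7 for
    four genotypes); adjustment is applied to the p-value rounded at
    reporting precision, matching how spectrum tables are published.
    Results do not depend on the input order of the spectra.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    spectra = sorted(spectra, key=lambda s: s.genotype)
    pairs = list(itertools.combinations(spectra, 2))
    if method == "chisq":
        results: list[ChiSqResult] = []
        m = len(pairs) + (1 if len(spectra) > 2 else 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(spectra) > 2:
                overall = chisq_independence(spectra_to_table(spectra))
                results.append(overall)
            for a, b in pairs:
                results.append(chisq_independence(spectra_to_table([a, b])))
        return [
            ChiSqResult(
                comparison=r.comparison,
                statistic=r.statistic,
                df=r.df,
                p=r.p,
                p_adjusted=bonferroni(round(r.p, p_decimals), m),
                m=m,
                small_expected=r.small_expected,
            )
            for r in results
        ]
    if method == "mc":
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(pairs))]
        return [
            mc_homogeneity(spectra_to_table([a, b]), n_iter=n_iter, seed=sd)
            for (a, b), sd in zip(pairs, seeds)
        ]
    raise ValueError("method must be 'chisq' or 'mc'")
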