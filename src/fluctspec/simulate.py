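"""Synthetic fluctuation-assay data with Luria-Delbrueck statistics.

The generator emulates the experiment end to end: parallel cultures grown by
synchronous doubling from a small inoculum, mutations arising per generation
as a Poisson process on cells born, each mutation founding a lineage that
doubles for the remaining generations (producing the characteristic jackpot
skew), plating with binomial thinning at a selective dilution, a Poisson
permissive-plate count, and a configurable admixture of phenotypically
silenced false-positive colonies that a verification step later identifies
and removes.

It also draws multinomial mutation spectra and builds reference ORF-like
sequences with embedded mononucleotide runs, so the classification and
comparison stages can be exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rates import Culture, CultureSet
from .spectrum import MutationSpectrum, scan_runs

__all__ = [
    "SimulationConfig",
    "SyntheticReference",
    "simulate_cultures",
    "simulate_spectrum",
    "generate_reference",
    "scan_runs",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and protocol parameters for one simulated assay.

    mu_true is the per-cell-division mutation rate; silencing_fraction the
    probability that an apparent resistant colony from the independent
    false-positive pool passes phenotype verification (Ura+), spanning the
    5-70% range seen with epigenetically silenced reporters.
    """

    mu_true: float
    n_initial: int
    n_final: float
    n_cultures: int
    plating_dilution_selective: float = 1.0
    plating_dilution_permissive: float = 1e5
    silencing_fraction: float = 0.0
    spectrum_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_true < 0:
            raise ValueError("mu_true must be non-negative")
        if not 0 < self.n_initial < self.n_final:
            raise ValueError("need 0 < n_initial < n_final")
        if self.n_cultures < 1:
            raise ValueError("need at least one culture")
        if not 0 <= self.silencing_fraction <= 1:
            raise ValueError("silencing_fraction must be in [0, 1]")
        if self.plating_dilution_selective < 1 or self.plating_dilution_permissive < 1:
            raise ValueError("dilution factors must be >= 1")
        if self.spectrum_proportions is not None:
            s = float(sum(self.spectrum_proportions))
            if abs(s - 1.0) > 1e-12:
                raise ValueError("spectrum proportions must sum to 1")
        if self.generations < 1:
            raise ValueError(
                "n_final/n_initial must allow at least one doubling"
            )

    @property
    def generations(self) -> int:
        """Number of synchronous doublings fitting below n_final."""
        return int(math.floor(math.log2(self.n_final / self.n_initial)))

    @property
    def n_final_actual(self) -> int:
        """Realized saturation census: n_initial * 2**generations."""
        return self.n_initial * 2 ** self.generations


@dataclass(frozen=True)
class SyntheticReference:
    """A synthetic ORF-like sequence plus its mononucleotide-run index.

    run_index lists (start, length, base) for every maximal run of length
    >= 2, 1-based inclusive start.
    """

    sequence: str
    run_index: tuple[tuple[int, int, str], ...]


def _ld_plated_counts(
    rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    """Selective-plate counts of true mutants, one per culture.

    Discrete-generation Luria-Delbrueck: at generation g (1..G) the number of
    cells born equals the pre-division population n_initial * 2**(g-1); new
    mutations ~ Poisson(mu * born), each founding a lineage of final size
    2**(G-g).  Plating is binomial thinning at 1/selective_dilution.
    """
    G = config.generations
    n_c = config.n_cultures
    totals = np.zeros(n_c, dtype=np.int64)
    for g in range(1, G + 1):
        born = config.n_initial * 2 ** (g - 1)
        new_mut = rng.poisson(config.mu_true * born, size=n_c)
        totals += new_mut * 2 ** (G - g)
    p_plate = 1.0 / config.plating_dilution_selective
    return rng.binomial(totals, p_plate)


def simulate_cultures(config: SimulationConfig) -> CultureSet:
    """Simulate one fluctuation assay; returns a CultureSet.

    Each culture record carries the selective count (true mutants plus
    silenced false positives), the permissive count, the dilutions, and the
    number of colonies the verification step identifies as silenced.  The
    false-positive pool is an independent draw of the same plating process
    thinned by silencing_fraction, so exclusion recovers the true counts.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_true, rng_false, rng_perm = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    true_plated = _ld_plated_counts(rng_true, config)
    apparent_pool = _ld_plated_counts(rng_false, config)
    silenced = rng_false.binomial(apparent_pool, config.silencing_fraction)
    permissive = rng_perm.poisson(
        config.n_final_actual / config.plating_dilution_permissive,
        size=config.n_cultures,
    )
    cultures = [
        Culture(
            selective_count=int(t + s),
            selective_dilution=config.plating_dilution_selective,
            permissive_count=int(p),
            permissive_dilution=config.plating_dilution_permissive,
            verified_silenced_count=int(s),
        )
        for t, s, p in zip(true_plated, silenced, permissive)
    ]
    return CultureSet(genotype="simulated", locus="synthetic", cultures=cultures)


def simulate_spectrum(
    proportions: Sequence[float],
    n: int,
    seed: int,
    categories: Sequence[str] | None = None,
    genotype: str = "simulated",
) -> MutationSpectrum:
    """Multinomial draw of n mutations over the spectrum categories."""
    props = np.asarray(proportions, dtype=float)
    if n < 0:
        raise ValueError("n must be non-negative")
    if abs(props.sum() - 1.0) > 1e-12:
        raise ValueError("proportions must sum to 1")
    if (props < 0).any():
        raise ValueError("proportions must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, props)
    if categories is None:
        categories = [f"category_{i}" for i in range(len(props))]
    return MutationSpectrum(
        genotype=genotype,
        counts=dict(zip(categories, (int(c) for c in counts))),
    )


def generate_reference(
    length: int,
    run_spec: Sequence[tuple[str, int]],
    seed: int,
    max_tries: int = 1000,
) -> SyntheticReference:
    """Random ACGT sequence with the requested mononucleotide runs embedded.

    Each (base, run_length) is placed at a random position such that
    placements do not overlap and flanks differ from the run base, so the
    embedded run is maximal and of exactly the requested length.  The
    returned run_index is produced by re-scanning the final sequence, so it
    also lists any runs of length >= 2 that arise by chance in the filler.
    """
    rng = np.random.default_rng(seed)
    for base, run_len in run_spec:
        if base not in _BASES:
            raise ValueError(f"invalid base {base!r}")
        if run_len < 1 or run_len + 2 > length:
            raise ValueError("embedded run does not fit within length")
    placed: list[tuple[int, int, str]] = []  # (start0, run_len, base)
    for base, run_len in run_spec:
        ok = False
        for _ in range(max_tries):
            # keep one flank position on each side inside the sequence
            start = int(rng.integers(1, length - run_len))
            lo, hi = start - 1, start + run_len + 1
            if all(hi <= s - 1 or lo >= s + l + 1 for s, l, _ in placed):
                placed.append((start, run_len, base))
                ok = True
                break
        if not ok:
            raise ValueError("could not place runs without overlap")
    seq = [rng.choice(list(_BASES)) for _ in range(length)]
    for start, run_len, base in placed:
        for k in range(start, start + run_len):
            seq[k] = base
        others = [b for b in _BASES if b != base]
        seq[start - 1] = rng.choice(others)
        if start + run_len < length:
            seq[start + run_len] = rng.choice(others)
    sequence = "".join(seq)
    return SyntheticReference(sequence=sequence, run_index=scan_runs(sequence))
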