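"""Published ura3 mutation spectra at the heterochromatic hmr::URA3 reporter.

These are the printed spectrum counts (50 sequenced FOA-resistant isolates
per genotype; 45 and 47 for the histone-acetyltransferase strains) and total
FOA-resistance mutation rates for the wild-type, mismatch-repair and
exonuclease deletion strains of a budding-yeast heterochromatin stability
study.  They serve as the worked real-data example for the partitioning,
repair-efficiency and spectrum-comparison stages, and let those stages run
offline.
"""

from __future__ import annotations

from .spectrum import CATEGORIES, MutationSpectrum

__all__ = [
    "hmr_spectra",
    "hmr_total_rates",
    "rtt109_spectra",
    "rtt109_total_rates",
    "BONFERRONI_FAMILY",
]

#: Family size used for the published pairwise spectrum comparisons:
#: six pairs among four genotypes plus the overall test.
BONFERRONI_FAMILY = 7

_HMR_COUNTS = {
    # category order: base substitution, 1-bp deletion, 1-bp insertion,
    # complex, other
    "wild type": (40, 7, 1, 1, 1),
    "msh2": (17, 25, 6, 1, 1),
    "msh2 exo1": (18, 24, 5, 2, 1),
    "exo1": (40, 7, 0, 3, 0),
}

#: Total FOA^R mutation rates per cell division at heterochromatic hmr::URA3,
#: and the number of sequenced mutations behind each spectrum.
_HMR_TOTALS = {
    "wild type": (60e-8, 50),
    "msh2": (500e-8, 50),
}

_RTT109_TOTALS = {
    "rtt109": (200e-8, 45),
    "rtt109 msh2": (1100e-8, 47),
}

_RTT109_COUNTS = {
    # counts back-derived from the published per-type rates; the complex
    # category of the double mutant is zero (printed as an upper bound)
    "rtt109 msh2": (18, 25, 2, 0, 2),
}


def hmr_spectra() -> list[MutationSpectrum]:
    """The four published spectra (wild type, msh2, msh2 exo1, exo1)."""
    return [
        MutationSpectrum(genotype=g, counts=dict(zip(CATEGORIES, counts)))
        for g, counts in _HMR_COUNTS.items()
    ]


def hmr_total_rates() -> dict[str, tuple[float, int]]:
    """Total mutation rate and spectrum size for wild type and msh2."""
    return dict(_HMR_TOTALS)


def rtt109_spectra() -> list[MutationSpectrum]:
    """Spectrum of the rtt109 msh2 double mutant (has a zero category)."""
    return [
        MutationSpectrum(genotype=g, counts=dict(zip(CATEGORIES, counts)))
        for g, counts in _RTT109_COUNTS.items()
    ]


def rtt109_total_rates() -> dict[str, tuple[float, int]]:
    """Total rates for the rtt109 single and rtt109 msh2 double mutant."""
    return dict(_RTT109_TOTALS)
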