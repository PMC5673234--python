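import pytest

from fluctspec import CATEGORIES, MutationSpectrum
from fluctspec.datasets import hmr_spectra, hmr_total_rates


@pytest.fixture(scope="session")
def published_spectra() -> list[MutationSpectrum]:
    """The four published hmr::URA3 spectra (50 mutations each)."""
    return hmr_spectra()


@pytest.fixture(scope="session")
def published_spectra_by_genotype(published_spectra):
    return {s.genotype: s for s in published_spectra}


@pytest.fixture(scope="session")
def published_totals():
    """Total FOA^R rates (per division) and n for wild type and msh2."""
    return hmr_total_rates()


@pytest.fixture
def simple_spectrum():
    return MutationSpectrum(
        genotype="toy",
        counts=dict(zip(CATEGORIES, (10, 5, 2, 1, 0))),
    )
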