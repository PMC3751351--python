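import numpy as np
import pytest

from kmerspec import KmerSpectrum, MixtureModel, model_expectation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def reference_mixture():
    """Known mixture used for noiseless round-trip checks: a bacterial-like
    spectrum with a dominant single-copy peak, a small 2-copy class and an
    rrn-like 7-copy class."""
    return MixtureModel(
        c=50.0, s=0.3, a=np.array([1e6, 1e4, 0, 0, 0, 0, 5e3]), x_min=1
    )


@pytest.fixture(scope="session")
def noiseless_spectrum(reference_mixture):
    """Spectrum whose bins are the rounded model expectations."""
    x = np.arange(1, 600)
    z = np.round(model_expectation(x, reference_mixture)).astype(int)
    keep = z > 0
    return KmerSpectrum(x[keep], z[keep])


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
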