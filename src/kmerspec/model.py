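"""Mixture model of a k-mer abundance spectrum.

The spectrum of a clonal genome sequenced at roughly even coverage is a
mixture of peaks at integer multiples n*c of the single-copy coverage c,
one peak per repeat copy number n.  Each peak is modelled as a negative
binomial (an over-dispersed Poisson) with mean n*c and dispersion s/n,
where the single shape parameter s absorbs coverage unevenness; s = 0
recovers the pure mixed-Poisson model.  The mixture coefficient a_n is the
amount of distinct sequence at copy number n, so the expected number of
distinct k-mers at abundance x is

    P(x) = sum_n a_n * NB(x; mean = n*c, alpha = s/n).

The negative binomial uses the standard mu-alpha convention with variance
mu + alpha * mu**2, which has the Poisson limit as alpha -> 0 that the
model requires.  From a fitted model, the distinct-k-mer total is sum a_n
and the genome size in bp-equivalents is sum n * a_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, xlogy

from .counting import KmerSpectrum, RepeatProfile

__all__ = [
    "MixtureModel",
    "nb_pmf",
    "nb_logpmf",
    "model_expectation",
    "spectrum_log_likelihood",
    "genome_size_estimate",
    "unique_kmer_estimate",
    "repeat_profile_from_model",
]

# below this dispersion the NB pmf is computed as Poisson: the gamma-form
# evaluation loses ~1e-8 absolute accuracy to cancellation at r = 1/alpha
# ~ 1e8 while the true NB-Poisson gap is still far smaller
_POISSON_ALPHA = 1e-8


def _poisson_logpmf(x: np.ndarray, mean: float) -> np.ndarray:
    return xlogy(x, mean) - mean - gammaln(x + 1.0)


def nb_logpmf(x, mean: float, alpha: float) -> np.ndarray:
    """Log pmf of the mu-alpha negative binomial (variance mu + alpha*mu^2).

    Evaluated through the gamma-function form with size r = 1/alpha and
    success probability r/(r+mu), so non-integer means are fine; alpha = 0
    (and alpha below ~1e-8) is the Poisson limit.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha < _POISSON_ALPHA:
        return _poisson_logpmf(x, mean)
    r = 1.0 / alpha
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1.0)
        + r * np.log(r / (r + mean))
        + x * np.log(mean / (r + mean))
    )


def nb_pmf(x, mean: float, alpha: float) -> np.ndarray:
    """Negative binomial pmf, mu-alpha parameterization; alpha=0 is Poisson."""
    return np.exp(nb_logpmf(x, mean, alpha))


@dataclass
class MixtureModel:
    """Fitted (or constructed) parameters of the spectrum mixture.

    Attributes
    ----------
    c : abundance of the principal (single-copy) peak, i.e. per-k-mer
        sequencing depth.
    s : overdispersion shape; component n has NB dispersion alpha = s/n.
    a : coefficients a_1..a_N, amount of distinct sequence (k-mers) at
        each copy number.
    x_min : low-abundance cutoff; bins below it are excluded from any
        likelihood, which is what makes the model robust to the
        error-k-mer spike at low abundance.
    """

    c: float
    s: float
    a: np.ndarray = field(default_factory=lambda: np.zeros(1))
    x_min: int = 1

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.s < 0:
            raise ValueError("s must be non-negative")
        if self.a.ndim != 1 or self.a.size < 1:
            raise ValueError("a must be a non-empty 1-D coefficient vector")
        if np.any(self.a < 0):
            raise ValueError("coefficients must be non-negative")
        if self.x_min < 1:
            raise ValueError("x_min must be >= 1")

    @property
    def n_components(self) -> int:
        return self.a.size

    def expectation(self, x) -> np.ndarray:
        return model_expectation(x, self)


def model_expectation(x, model: MixtureModel) -> np.ndarray:
    """Expected number of distinct k-mers at abundance x under the model.

    P(x) = sum_n a_n * NB(x; mean = c*n, alpha = s/n); with s = 0 this is
    the mixed-Poisson model, and with a single component the plain
    a_1 * Poisson(x; c).
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    out = np.zeros_like(x_arr)
    for n, a_n in enumerate(model.a, start=1):
        if a_n > 0:
            out += a_n * nb_pmf(x_arr, model.c * n, model.s / n)
    return float(out[0]) if scalar else out


def spectrum_log_likelihood(
    spectrum: KmerSpectrum,
    model: MixtureModel,
    x_range: tuple[int, int] | None = None,
) -> float:
    """Poisson log-likelihood of observed bin counts under the mixture.

    Each observed count z_i is treated as a Poisson draw with mean P(i);
    every integer abundance in ``x_range`` contributes, with z_i = 0 for
    bins absent from the spectrum.  Returns -inf if the model assigns zero
    mass to an occupied bin.
    """
    if x_range is None:
        x_range = (model.x_min, spectrum.max_abundance)
    lo, hi = int(x_range[0]), int(x_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("invalid x_range")
    x = np.arange(lo, hi + 1, dtype=float)
    z = spectrum.dense_counts(lo, hi).astype(float)
    lam = model_expectation(x, model)
    if np.any((lam == 0) & (z > 0)):
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(z, lam) - lam - gammaln(z + 1.0)
    return float(np.sum(ll))


def genome_size_estimate(model_or_profile) -> float:
    """Genome size in bp-equivalents: sum of n * a_n."""
    if isinstance(model_or_profile, RepeatProfile):
        return model_or_profile.genome_size
    m = model_or_profile
    n = np.arange(1, m.a.size + 1)
    return float(np.dot(n, m.a))


def unique_kmer_estimate(model_or_profile) -> float:
    """Distinct-k-mer total: sum of the a coefficients."""
    if isinstance(model_or_profile, RepeatProfile):
        return model_or_profile.unique_total
    return float(np.sum(model_or_profile.a))


def repeat_profile_from_model(model: MixtureModel) -> RepeatProfile:
    """Per-copy-number table of the fitted coefficients.

    Rows with a_n exactly zero are dropped; near-zero fitted coefficients
    are kept as-is.
    """
    n = np.arange(1, model.a.size + 1)
    keep = model.a > 0
    return RepeatProfile(n[keep], model.a[keep])
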