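"""Maximum-likelihood fitting of the spectrum mixture.

The estimator mirrors how a human reads a spectrum: locate the principal
(single-copy) peak, mask the low-abundance error spike, fit the principal
peak's height/position/width, then extend the model one copy-number at a
time — each new coefficient seeded by weighted least squares on the
residual counts near its expected position — re-optimising all parameters
jointly at every stage.  Successive low-order fits stabilise the final
high-dimensional optimisation, which plain joint ML from a cold start does
not survive on real spectra.

The public surface is statsmodels-like: build a :class:`SpectrumMixture`
from a spectrum (or a histogram file, or reads), call :meth:`fit`, and
read estimates off the returned :class:`SpectrumMixtureResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, xlogy

from .counting import KmerSpectrum, RepeatProfile
from .model import (
    MixtureModel,
    genome_size_estimate,
    model_expectation,
    nb_pmf,
    repeat_profile_from_model,
    spectrum_log_likelihood,
    unique_kmer_estimate,
)

__all__ = [
    "FitConfig",
    "InsufficientCoverageError",
    "SpectrumMixture",
    "SpectrumMixtureResults",
    "initial_peak_estimate",
    "fit_spectrum",
]

logger = logging.getLogger(__name__)

# Overdispersion box for the optimiser.  The lower edge is not 0: the
# analytic gradient w.r.t. s degenerates numerically as s -> 0 (cancelling
# digamma terms amplified by 1/s^2), and at s = 1e-4 the NB is already
# within a fraction of a percent of Poisson at bacterial coverages.
_S_MIN = 1e-4
_S_MAX = 100.0


class InsufficientCoverageError(ValueError):
    """No resolvable principal peak: coverage too low for inference."""


def initial_peak_estimate(spectrum: KmerSpectrum) -> int:
    """Abundance of the principal peak, from the transformed series x*z_x.

    Scans from low abundance, passes the initial descending error region
    (up to the first local minimum) and returns the abundance maximising
    x*z_x beyond it, ties broken toward smaller x.  If the series rises
    immediately (no error spike) this is the global argmax.  A spectrum
    that decreases monotonically everywhere has no resolvable peak and
    raises :class:`InsufficientCoverageError`.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    t = spectrum.abundance * spectrum.count
    rises = np.nonzero(np.diff(t) > 0)[0]
    if rises.size == 0:
        raise InsufficientCoverageError(
            "spectrum decreases monotonically: no principal peak resolvable "
            "(coverage likely below ~10x)"
        )
    valley = rises[0]
    peak = valley + int(np.argmax(t[valley:]))
    return int(spectrum.abundance[peak])


@dataclass
class FitConfig:
    """Knobs of the staged fit.

    max_copy: highest modelled copy number N (components sit at n*c for
        n = 1..N).
    min_abundance: manual low-abundance cutoff overriding the automatic
        half-peak rule (needed e.g. for ultra-high-coverage tiny genomes
        where the error spike swamps the peak detector).
    max_components: cap on the number of mixture terms actually fitted
        (1 constrains to a single-peak fit).
    tol: relative log-likelihood improvement declaring a stage converged.
    max_iter: optimiser iteration cap per stage.
    x_max: upper abundance bound for the fitted range (default: data- and
        model-driven, min(max observed, (N+0.5)*c)).
    """

    max_copy: int = 30
    min_abundance: int | None = None
    max_components: int | None = None
    tol: float = 1e-8
    max_iter: int = 500
    x_max: int | None = None

    def __post_init__(self) -> None:
        if self.max_copy < 1:
            raise ValueError("max_copy must be >= 1")
        if self.min_abundance is not None and self.min_abundance < 1:
            raise ValueError("min_abundance must be positive")
        if self.max_components is not None and self.max_components < 1:
            raise ValueError("max_components must be >= 1")


def _nb_logpmf_matrix(x: np.ndarray, c: float, s: float, n_comp: int):
    """Log pmf of all components on the grid, plus pieces for gradients.

    Returns (logp, r, mu) with logp of shape (n_comp, len(x)).
    """
    ns = np.arange(1, n_comp + 1, dtype=float)
    mu = c * ns
    r = ns / s
    X = x[None, :]
    logp = (
        gammaln(X + r[:, None])
        - gammaln(r)[:, None]
        - gammaln(X + 1.0)
        + (r * np.log(r / (r + mu)))[:, None]
        + X * np.log(mu / (r + mu))[:, None]
    )
    return logp, r, mu, ns


def _negloglike_and_grad(theta, x, z, n_comp, c_ref, a_ref):
    """Negative Poisson log-likelihood (constants dropped) and gradient.

    theta = [c/c_ref, s, a_1/a_ref .. a_n/a_ref].
    """
    c = theta[0] * c_ref
    s = theta[1]
    a = theta[2:] * a_ref

    logp, r, mu, ns = _nb_logpmf_matrix(x, c, s, n_comp)
    P = np.exp(logp)
    # floor keeps z/lam finite where the model underflows; the resulting
    # ~ -27.6 log-penalty per count still drives mass back to such bins
    lam = np.maximum(a @ P, 1e-12)
    nll = -float(np.sum(xlogy(z, lam) - lam))

    w = z / lam - 1.0  # d(LL)/d(lam)

    grad_a = P @ w

    X = x[None, :]
    dlogp_dc = ns[:, None] * (
        X / mu[:, None] - (X + r[:, None]) / (mu[:, None] + r[:, None])
    )
    grad_c = float(np.sum((a[:, None] * P * dlogp_dc) @ w))

    dlogp_dr = (
        digamma(X + r[:, None])
        - digamma(r)[:, None]
        + np.log(r / (r + mu))[:, None]
        + (mu[:, None] - X) / (r[:, None] + mu[:, None])
    )
    dr_ds = -ns / (s * s)
    grad_s = float(np.sum((a * dr_ds)[:, None] * P * dlogp_dr @ w))

    grad = -np.concatenate(([grad_c * c_ref], [grad_s], grad_a * a_ref))
    return nll, grad


def _partial_loglike(x, z, c, s, a):
    """Log-likelihood without the z! constant, for within-fit comparisons."""
    logp, *_ = _nb_logpmf_matrix(x, c, s, len(a))
    lam = np.maximum(a @ np.exp(logp), 1e-12)
    return float(np.sum(xlogy(z, lam) - lam))


def _optimize_stage(x, z, c_init, s_init, a_init, config: FitConfig):
    """Jointly maximise the likelihood from the given start; never return a
    point worse than the start."""
    n_comp = len(a_init)
    c_ref = float(c_init)
    a_ref = max(float(np.sum(z)), 1.0)
    theta0 = np.concatenate(
        ([1.0], [float(np.clip(s_init, _S_MIN, _S_MAX))], np.asarray(a_init) / a_ref)
    )
    bounds = [(0.05, None), (_S_MIN, _S_MAX)] + [(0.0, None)] * n_comp
    res = minimize(
        _negloglike_and_grad,
        theta0,
        args=(x, z, n_comp, c_ref, a_ref),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_iter, "ftol": config.tol},
    )
    start = (c_init, float(np.clip(s_init, _S_MIN, _S_MAX)), np.asarray(a_init, float))
    fitted = (float(res.x[0] * c_ref), float(res.x[1]), res.x[2:] * a_ref)
    ll_start = _partial_loglike(x, z, *start)
    ll_fit = _partial_loglike(x, z, *fitted)
    if not np.isfinite(ll_fit) or ll_fit < ll_start:
        return start[0], start[1], start[2], ll_start, int(res.nit), False
    return fitted[0], fitted[1], fitted[2], ll_fit, int(res.nit), bool(res.success)


def _wls_coefficient_init(spectrum, x_min, hi, c, s, a, n):
    """Seed a_n by weighted least squares of residual counts against the
    component shape over [(n-0.5)c, (n+0.5)c], weights 1/max(z,1)."""
    lo_w = max(x_min, int(round((n - 0.5) * c)))
    hi_w = min(hi, int(round((n + 0.5) * c)))
    if hi_w < lo_w:
        return 0.0
    xw = np.arange(lo_w, hi_w + 1, dtype=float)
    zw = spectrum.dense_counts(lo_w, hi_w).astype(float)
    current = MixtureModel(c=c, s=max(s, 0.0), a=a, x_min=x_min)
    resid = zw - model_expectation(xw, current)
    g = nb_pmf(xw, c * n, s / n)
    w = 1.0 / np.maximum(zw, 1.0)
    denom = float(np.sum(w * g * g))
    if denom <= 0:
        return 0.0
    return max(float(np.sum(w * resid * g)) / denom, 0.0)


class SpectrumMixture:
    """Mixture model of a k-mer abundance spectrum, ready to fit.

    Parameters
    ----------
    spectrum : KmerSpectrum
        Observed abundance histogram.
    config : FitConfig, optional
        Fit settings; keyword arguments are accepted as a shorthand
        (``SpectrumMixture(spec, max_copy=10)``).
    """

    def __init__(self, spectrum: KmerSpectrum, config: FitConfig | None = None, **kwargs):
        if config is not None and kwargs:
            raise TypeError("pass either config or keyword settings, not both")
        self.spectrum = spectrum
        self.config = config if config is not None else FitConfig(**kwargs)

    @classmethod
    def from_histogram(cls, path: str, **kwargs) -> "SpectrumMixture":
        """Build from a two-column histogram file (e.g. jellyfish histo)."""
        from .io import read_histogram

        return cls(read_histogram(path), **kwargs)

    @classmethod
    def from_sequences(cls, sequences, k: int = 21, **kwargs) -> "SpectrumMixture":
        """Count k-mers in an in-memory sequence collection and build."""
        from .counting import build_spectrum, count_kmers

        return cls(build_spectrum(count_kmers(sequences, k)), **kwargs)

    @classmethod
    def from_reads(cls, paths, k: int = 21, **kwargs) -> "SpectrumMixture":
        """Count k-mers in FASTA/FASTQ files (plain or gzipped) and build."""
        from .io import read_sequences

        return cls.from_sequences(read_sequences(paths), k=k, **kwargs)

    def loglike(self, model: MixtureModel, x_range=None) -> float:
        return spectrum_log_likelihood(self.spectrum, model, x_range)

    # ------------------------------------------------------------------

    def _principal_peak(self):
        cfg = self.config
        work = self.spectrum
        if cfg.min_abundance is not None:
            work = work.restrict(lo=cfg.min_abundance)
            if len(work) == 0:
                raise ValueError("manual cutoff excludes the entire spectrum")
        try:
            return initial_peak_estimate(work)
        except InsufficientCoverageError:
            if cfg.min_abundance is None:
                raise
            # above a manual cutoff a bare argmax is an acceptable seed
            t = work.abundance * work.count
            return int(work.abundance[int(np.argmax(t))])

    def fit(self) -> "SpectrumMixtureResults":
        """Run the staged maximum-likelihood fit."""
        cfg = self.config
        spec = self.spectrum
        if len(spec) == 0:
            raise ValueError("cannot fit an empty spectrum")

        c0 = self._principal_peak()
        x_max_obs = spec.max_abundance
        if cfg.x_max is not None:
            x_max_obs = min(x_max_obs, cfg.x_max)
        n_terms = min(cfg.max_components or cfg.max_copy, cfg.max_copy)

        manual = cfg.min_abundance or 1
        x_min = max(manual, int(round(c0 / 2)), 1)
        stages: list[dict] = []

        # stage 1: principal peak (a1, c, s) on [x_min, 1.5 c], multi-start
        # over the dispersion (the single-peak likelihood has a spurious
        # broad-peak optimum that a bad s start can fall into); the
        # half-peak cutoff is bootstrapped from the mode estimate and
        # recomputed once if the fitted c moves by more than 10%
        c_seed = float(c0)
        for attempt in range(2):
            hi = min(x_max_obs, int(round(1.5 * c_seed)))
            if hi <= x_min:
                hi = min(x_max_obs, x_min + max(3, int(round(0.5 * c_seed))))
            x = np.arange(x_min, hi + 1, dtype=float)
            z = spec.dense_counts(x_min, hi).astype(float)
            a1_init = max(float(z.sum()), 1.0)
            best = None
            for s_start in (0.05, 0.3, 1.0):
                cand = _optimize_stage(x, z, c_seed, s_start, np.array([a1_init]), cfg)
                if best is None or cand[3] > best[3]:
                    best = cand
            c, s, a, ll, nit, ok = best
            stages.append(
                {"stage": 1, "x_range": (x_min, hi), "loglike": ll, "nit": nit,
                 "success": ok, "c": c, "s": s, "a": list(a)}
            )
            logger.info("stage 1 (attempt %d): c=%.3f s=%.4f ll=%.2f", attempt + 1, c, s, ll)
            new_x_min = max(manual, int(round(c / 2)), 1)
            if abs(c - c_seed) <= 0.1 * c_seed or new_x_min == x_min:
                break
            x_min, c_seed = new_x_min, c

        # stages 2..n: extend one copy number at a time, WLS-seeded,
        # joint re-optimisation; never accept a worse likelihood than the
        # previous model carried onto the widened range
        for n in range(2, n_terms + 1):
            if (n - 0.5) * c > x_max_obs:
                # the mixture terminates at the highest observed abundance:
                # a component whose window lies wholly beyond the data has
                # nothing to fit and would only soak up edge-bin mass
                break
            hi = min(x_max_obs, int(round((n + 0.5) * c)))
            if hi <= x_min:
                a = np.append(a, 0.0)
                continue
            a_new = _wls_coefficient_init(spec, x_min, hi, c, s, a, n)
            x = np.arange(x_min, hi + 1, dtype=float)
            z = spec.dense_counts(x_min, hi).astype(float)
            a_start = np.append(a, a_new)
            c1, s1, a1, ll, nit, ok = _optimize_stage(x, z, c, s, a_start, cfg)
            ll_prev = _partial_loglike(x, z, c, s, np.append(a, 0.0))
            if ll < ll_prev:  # keep the lower-order model, zero-extended
                c1, s1, a1, ll, ok = c, s, np.append(a, 0.0), ll_prev, False
            c, s, a = c1, s1, a1
            stages.append(
                {"stage": n, "x_range": (x_min, hi), "loglike": ll, "nit": nit,
                 "success": ok, "c": c, "s": s, "a": list(a)}
            )
            logger.info("stage %d: c=%.3f s=%.4f a_%d=%.1f ll=%.2f", n, c, s, n, a[-1], ll)

        # final joint polish over the full masked range
        hi_final = min(x_max_obs, int(round((len(a) + 0.5) * c)))
        hi_final = max(hi_final, x_min + 1)
        x = np.arange(x_min, hi_final + 1, dtype=float)
        z = spec.dense_counts(x_min, hi_final).astype(float)
        c, s, a, ll, nit, ok = _optimize_stage(x, z, c, s, a, cfg)
        stages.append(
            {"stage": "final", "x_range": (x_min, hi_final), "loglike": ll,
             "nit": nit, "success": ok, "c": c, "s": s, "a": list(a)}
        )

        model = MixtureModel(c=c, s=s, a=a, x_min=x_min)
        llf = spectrum_log_likelihood(spec, model, (x_min, hi_final))

        below = spec.abundance < x_min
        above = spec.abundance > hi_final
        res = SpectrumMixtureResults(
            model=model,
            llf=llf,
            c0=c0,
            x_range=(x_min, hi_final),
            stages=stages,
            spectrum=spec,
            config=cfg,
            excluded_low_instances=int(
                np.dot(spec.abundance[below], spec.count[below])
            ),
            unmodeled_high_instances=int(
                np.dot(spec.abundance[above], spec.count[above])
            ),
        )
        logger.info(
            "fit done: c=%.3f s=%.4f genome=%.0f bp unique=%.0f kmers",
            c, s, res.genome_size, res.unique_kmers,
        )
        return res


@dataclass
class SpectrumMixtureResults:
    """Estimates, uncertainty proxies and diagnostics from a spectrum fit."""

    model: MixtureModel
    llf: float
    c0: int
    x_range: tuple[int, int]
    stages: list
    spectrum: KmerSpectrum
    config: FitConfig
    excluded_low_instances: int = 0
    unmodeled_high_instances: int = 0

    # -- parameter access ------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Parameter vector [c, s, a_1..a_N]."""
        return np.concatenate(([self.model.c, self.model.s], self.model.a))

    @property
    def c(self) -> float:
        return self.model.c

    @property
    def s(self) -> float:
        return self.model.s

    @property
    def a(self) -> np.ndarray:
        return self.model.a

    # -- derived quantities ----------------------------------------------
    @property
    def genome_size(self) -> float:
        """Estimated genome size, bp-equivalents (sum n * a_n)."""
        return genome_size_estimate(self.model)

    @property
    def unique_kmers(self) -> float:
        """Estimated distinct-k-mer total (sum a_n)."""
        return unique_kmer_estimate(self.model)

    @property
    def coverage(self) -> float:
        """Per-k-mer sequencing depth (the principal peak position)."""
        return self.model.c

    @property
    def reliable(self) -> bool:
        """False when coverage is below ~10x, where inference is unsupported."""
        return self.model.c >= 10.0

    def predict(self, x) -> np.ndarray:
        """Expected distinct-k-mer counts at abundance(s) x."""
        return model_expectation(x, self.model)

    def repeat_profile(self) -> RepeatProfile:
        return repeat_profile_from_model(self.model)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "          Spectrum Mixture Model Results",
            "=" * 52,
            f"Distinct k-mers observed   {self.spectrum.distinct:>18,}",
            f"Fitted abundance range     {str(self.x_range):>18}",
            f"Principal peak seed c0     {self.c0:>18}",
            f"Coverage c                 {m.c:>18.3f}",
            f"Overdispersion s           {m.s:>18.4f}",
            f"Components fitted          {m.n_components:>18}",
            f"Log-likelihood             {self.llf:>18.2f}",
            f"Genome size (bp-equiv)     {self.genome_size:>18,.0f}",
            f"Unique k-mers              {self.unique_kmers:>18,.0f}",
            f"Excluded low-x instances   {self.excluded_low_instances:>18,}",
            f"Unmodeled high-x instances {self.unmodeled_high_instances:>18,}",
            "-" * 52,
            f"{'copy n':>6} {'unique bp':>14} {'total bp':>14}",
        ]
        for n, a_n in enumerate(m.a, start=1):
            if a_n >= 0.5:
                lines.append(f"{n:>6} {a_n:>14,.0f} {n * a_n:>14,.0f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "c": self.model.c,
            "s": self.model.s,
            "a": self.model.a.tolist(),
            "x_min": self.model.x_min,
            "x_range": list(self.x_range),
            "c0": self.c0,
            "log_likelihood": self.llf,
            "genome_size": self.genome_size,
            "unique_kmers": self.unique_kmers,
            "reliable": self.reliable,
            "excluded_low_instances": self.excluded_low_instances,
            "unmodeled_high_instances": self.unmodeled_high_instances,
            "config": asdict(self.config),
            "stages": [
                {**st, "x_range": list(st["x_range"])} for st in self.stages
            ],
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "wt") as fh:
                fh.write(text)
        return text


def fit_spectrum(spectrum: KmerSpectrum, config: FitConfig | None = None, **kwargs):
    """Functional wrapper: fit a spectrum and return the results object."""
    return SpectrumMixture(spectrum, config=config, **kwargs).fit()
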