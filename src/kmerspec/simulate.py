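"""Synthetic genomes with prescribed repeat architecture, and shotgun reads.

The simulator provides the regime the mixture model assumes — uniform read
sampling over the genome, hence near-Poisson per-copy abundance peaks —
plus independent per-base substitution errors that populate the
low-abundance error spike.  It deliberately models no coverage bias,
no indels, no quality-dependent errors and no read pairing: pairing is
irrelevant to spectra, and real-data coverage unevenness is absorbed by
the model's overdispersion parameter rather than simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counting import (
    RepeatProfile,
    _DECODE,
    encode_bases,
    genome_copy_table,
)

__all__ = [
    "SyntheticGenomeSpec",
    "ReadSimParams",
    "generate_genome",
    "simulate_reads",
    "recovery_experiment",
]

_SPACER = 50  # unique separator between embedded segments, bp


@dataclass
class SyntheticGenomeSpec:
    """Declarative repeat architecture of a test genome.

    ``blocks`` lists (copy_number, unique_length_bp) pairs: each block is a
    random sequence of the given length embedded copy_number times,
    separated by unique random spacers.  A (1, L) block is plain
    single-copy sequence.
    """

    blocks: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    gc: float = 0.5

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block required")
        for n, length in self.blocks:
            if n < 1 or length < 1:
                raise ValueError("copy numbers and lengths must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")

    @property
    def implied_length(self) -> int:
        """Repeat-block sequence total, excluding spacers."""
        return sum(n * length for n, length in self.blocks)


@dataclass
class ReadSimParams:
    """Shotgun read sampling settings (single-end, uniform starts)."""

    read_length: int = 76
    depth: float = 60.0
    error_rate: float = 0.0
    seed: int = 0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def generate_genome(spec: SyntheticGenomeSpec, k: int = 21) -> tuple[str, RepeatProfile]:
    """Emit a genome realising the spec, with its exact repeat profile.

    Repeat copies are dispersed in shuffled order and separated by unique
    random spacers, so repeats are interspersed rather than tandem.  The
    returned profile is computed by exact counting on the emitted sequence,
    so chance k-mer collisions between "unique" segments are reflected
    honestly.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[np.ndarray] = []
    for n, length in spec.blocks:
        block = _random_codes(rng, length, spec.gc)
        segments.extend([block] * n)
    order = rng.permutation(len(segments))

    parts: list[np.ndarray] = []
    for i, idx in enumerate(order):
        if i:
            parts.append(_random_codes(rng, _SPACER, spec.gc))
        parts.append(segments[idx])
    codes = np.concatenate(parts)
    if codes.size < k:
        raise ValueError("spec implies a genome shorter than k")
    genome = _DECODE[codes].tobytes().decode("ascii")
    return genome, genome_copy_table([genome], k)


def simulate_reads(genome: str, params: ReadSimParams) -> list[str]:
    """Draw uniform shotgun reads from both strands with substitution errors.

    Reads are emitted until total bases reach depth * genome length (so the
    total is within one read length of that product).  Each base is
    substituted independently with probability ``error_rate``, uniformly
    over the three alternatives.  Deterministic given the seed.
    """
    G = len(genome)
    L = params.read_length
    if G < L:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(params.seed)
    n_reads = int(np.ceil(params.depth * G / L))

    codes = encode_bases(genome)
    if params.error_rate > 0 and np.any(codes > 3):
        raise ValueError("genome contains non-ACGT characters")
    if params.circular:
        starts = rng.integers(0, G, size=n_reads)
        idx = (starts[:, None] + np.arange(L)) % G
    else:
        starts = rng.integers(0, G - L + 1, size=n_reads)
        idx = starts[:, None] + np.arange(L)
    mat = codes[idx]

    rev = rng.random(n_reads) < 0.5
    mat[rev] = (3 - mat[rev])[:, ::-1]

    if params.error_rate > 0:
        hit = rng.random(mat.shape) < params.error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
        mat = np.where(hit, (mat + shift) % 4, mat)

    raw = _DECODE[mat].tobytes().decode("ascii")
    return [raw[i * L : (i + 1) * L] for i in range(n_reads)]


def recovery_experiment(
    spec: SyntheticGenomeSpec,
    params: ReadSimParams,
    config=None,
    k: int = 21,
) -> dict:
    """Generate -> simulate -> count -> fit, and compare against truth.

    Returns a report with the true and estimated genome size, per-copy
    comparisons for every copy number present in the truth, and fit
    diagnostics.  A fit that fails for lack of a resolvable peak, or whose
    fitted coverage is below ~10x, is flagged rather than trusted.
    """
    from .fitting import InsufficientCoverageError, SpectrumMixture

    genome, truth = generate_genome(spec, k)
    reads = simulate_reads(genome, params)
    mix = SpectrumMixture.from_sequences(reads, k=k, config=config)

    report: dict = {
        "true_genome_size": float(len(genome)),
        "true_profile": {
            int(n): float(u)
            for n, u in zip(truth.copy_number, truth.unique_amount)
        },
        "k": k,
        "depth": params.depth,
        "error_rate": params.error_rate,
    }
    try:
        results = mix.fit()
    except InsufficientCoverageError as err:
        report.update(status="failed_low_coverage", message=str(err))
        return report

    est_profile = results.repeat_profile()
    copy_rows = {}
    for n in truth.copy_number:
        n = int(n)
        true_u = truth.unique_at(n)
        est_u = est_profile.unique_at(n)
        copy_rows[n] = {
            "true_unique": true_u,
            "estimated_unique": est_u,
            "rel_error": (est_u - true_u) / true_u if true_u else float("nan"),
        }
    report.update(
        status="ok" if results.reliable else "unreliable_low_coverage",
        estimated_genome_size=results.genome_size,
        genome_size_rel_error=(results.genome_size - len(genome)) / len(genome),
        estimated_unique_kmers=results.unique_kmers,
        coverage=results.c,
        overdispersion=results.s,
        copy_numbers=copy_rows,
        results=results,
    )
    return report
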