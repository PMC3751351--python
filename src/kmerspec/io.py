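"""Readers and writers for sequence files, histograms, and profile tables."""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator

import numpy as np

from .counting import KmerSpectrum, RepeatProfile

__all__ = [
    "read_sequences",
    "read_histogram",
    "write_histogram",
    "write_fasta",
    "write_fastq",
    "write_repeat_profile",
]

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = os.path.splitext(name)[1].lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def read_sequences(paths: str | Iterable[str], fmt: str | None = None) -> Iterator[str]:
    """Yield sequences from FASTA/FASTQ files (plain or gzipped).

    Multiple files are concatenated; format is inferred per file from the
    extension unless ``fmt`` is given.
    """
    from Bio import SeqIO

    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    for path in paths:
        this_fmt = fmt or _sniff_format(path)
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, this_fmt):
                yield str(rec.seq)


def read_histogram(path: str, k: int | None = None) -> KmerSpectrum:
    """Read a two-column abundance histogram (``x  z_x`` per line).

    The format matches common k-mer-counter histogram output (e.g.
    jellyfish ``histo``), so externally counted histograms can be fitted
    directly.  Lines starting with ``#`` are ignored.
    """
    xs: list[int] = []
    zs: list[int] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed histogram line: {line!r}")
            xs.append(int(parts[0]))
            zs.append(int(round(float(parts[1]))))
    order = np.argsort(xs)
    return KmerSpectrum(np.asarray(xs)[order], np.asarray(zs)[order], k)


def write_histogram(spectrum: KmerSpectrum, path: str) -> None:
    with open(path, "wt") as fh:
        for x, z in zip(spectrum.abundance, spectrum.count):
            fh.write(f"{int(x)} {int(z)}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[str], path: str, prefix: str = "read") -> None:
    """Write reads with constant placeholder qualities."""
    with open(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_repeat_profile(profile: RepeatProfile, path: str) -> None:
    """Write a profile as TSV with a final cumulative row."""
    with open(path, "wt") as fh:
        fh.write("copy_number\tunique_bp\ttotal_bp\n")
        for n, u, t in zip(
            profile.copy_number, profile.unique_amount, profile.total_amount
        ):
            fh.write(f"{int(n)}\t{u:.0f}\t{t:.0f}\n")
        fh.write(f"cumulative\t{profile.unique_total:.0f}\t{profile.genome_size:.0f}\n")
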