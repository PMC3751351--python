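"""Canonical k-mer counting, abundance spectra, and exact copy-number tables.

A k-mer and its reverse complement are two readings of the same piece of
double-stranded DNA, so they are collapsed onto a single *canonical*
representative: the lexicographically smaller of the pair.  All counting in
this package is canonical.  K-mers are packed into 2-bit-per-base integer
codes (A=0, C=1, G=2, T=3), which makes the lexicographic minimum equal to
the numeric minimum and lets the whole pipeline run on vectorised numpy
arrays; the supported k range is 1-31 so a code fits a signed 64-bit word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "KmerCountTable",
    "KmerSpectrum",
    "RepeatProfile",
    "canonicalize",
    "count_kmers",
    "build_spectrum",
    "genome_copy_table",
    "n_canonical_kmers",
]

MAX_K = 31

# base -> 2-bit code; 4 marks anything that is not A/C/G/T (case-folded)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


def encode_bases(seq: str | bytes) -> np.ndarray:
    """Map a sequence to 2-bit codes (uint8); non-ACGT positions become 4."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit k-mer code back into an A/C/G/T string."""
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the canonical form of a k-mer.

    The canonical form is the lexicographic minimum of the k-mer and its
    reverse complement; it is idempotent.  Raises ``ValueError`` for
    non-ACGT characters (callers counting reads simply skip such windows).
    """
    kmer = kmer.upper()
    if not kmer or any(c not in "ACGT" for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def n_canonical_kmers(k: int) -> int:
    """Number of distinct canonical k-mers over the ACGT alphabet.

    Odd k: no k-mer is its own reverse complement, so 4^k / 2.
    Even k: the 4^(k/2) palindromic k-mers are their own reverse
    complement, giving (4^k + 4^(k/2)) / 2.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k % 2:
        return 4**k // 2
    return (4**k + 4 ** (k // 2)) // 2


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical integer codes of every valid k-window in a code array.

    ``codes`` may contain the sentinel 4 (invalid base / sequence
    separator); windows touching a sentinel are dropped.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    invalid = (codes > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(invalid)))
    ok = (cum[k:] - cum[:-k]) == 0

    c = codes.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | c[j : j + n]
        rev = (rev << 2) | (3 - c[k - 1 - j : k - 1 - j + n])
    return np.minimum(fwd, rev)[ok]


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers, stored as sorted packed codes.

    Behaves like a read-only mapping from canonical k-mer string to its
    occurrence count; lookups accept either strand.
    """

    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return self.codes.size

    @property
    def distinct(self) -> int:
        """Number of distinct canonical k-mers."""
        return self.codes.size

    @property
    def total_instances(self) -> int:
        """Total number of counted k-mer windows."""
        return int(self.counts.sum())

    def _lookup(self, kmer: str) -> int:
        kmer = canonicalize(kmer)
        if len(kmer) != self.k:
            raise KeyError(kmer)
        code = 0
        for ch in kmer:
            code = (code << 2) | int(_ENCODE[ord(ch)])
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def __getitem__(self, kmer: str) -> int:
        count = self._lookup(kmer)
        if count == 0:
            raise KeyError(kmer)
        return count

    def get(self, kmer: str, default: int = 0) -> int:
        count = self._lookup(kmer)
        return count if count else default

    def __contains__(self, kmer: str) -> bool:
        return self._lookup(kmer) > 0

    def items(self) -> Iterator[tuple[str, int]]:
        for code, count in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(count)

    def as_dict(self) -> dict[str, int]:
        return dict(self.items())


@dataclass
class KmerSpectrum:
    """Abundance spectrum: number of distinct k-mers ``count[i]`` seen
    exactly ``abundance[i]`` times.  Abundances are strictly increasing.

    ``k`` is metadata and may be None for externally produced histograms.
    """

    abundance: np.ndarray
    count: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.abundance.size != self.count.size:
            raise ValueError("abundance and count must have equal length")
        if self.abundance.size:
            if np.any(np.diff(self.abundance) <= 0):
                raise ValueError("abundances must be strictly increasing")
            if self.abundance[0] < 1 or np.any(self.count < 0):
                raise ValueError("abundances must be >= 1 and counts >= 0")

    def __len__(self) -> int:
        return self.abundance.size

    @property
    def total_instances(self) -> int:
        """Sum of x * z_x: total k-mer windows in the source data."""
        return int(np.dot(self.abundance, self.count))

    @property
    def distinct(self) -> int:
        """Sum of z_x: distinct canonical k-mers in the source data."""
        return int(self.count.sum())

    @property
    def max_abundance(self) -> int:
        if not self.abundance.size:
            raise ValueError("empty spectrum")
        return int(self.abundance[-1])

    def dense_counts(self, lo: int, hi: int) -> np.ndarray:
        """Counts z_x on the inclusive integer grid lo..hi, zero-filled."""
        z = np.zeros(hi - lo + 1, dtype=np.int64)
        sel = (self.abundance >= lo) & (self.abundance <= hi)
        z[self.abundance[sel] - lo] = self.count[sel]
        return z

    def restrict(self, lo: int = 1, hi: int | None = None) -> "KmerSpectrum":
        sel = self.abundance >= lo
        if hi is not None:
            sel &= self.abundance <= hi
        return KmerSpectrum(self.abundance[sel], self.count[sel], self.k)


@dataclass
class RepeatProfile:
    """Per-copy-number breakdown of a genome.

    Row n gives the amount of distinct ("unique") sequence present at copy
    number n, measured in k-mers, which at bacterial scale is numerically
    interchangeable with base pairs (every base starts one k-mer window
    except at sequence ends); totals are labelled bp-equivalents.
    """

    copy_number: np.ndarray
    unique_amount: np.ndarray

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=np.int64)
        self.unique_amount = np.asarray(self.unique_amount, dtype=float)
        if self.copy_number.size != self.unique_amount.size:
            raise ValueError("ragged profile")
        if self.copy_number.size:
            if np.any(np.diff(self.copy_number) <= 0) or self.copy_number[0] < 1:
                raise ValueError("copy numbers must be strictly increasing and >= 1")
            if np.any(self.unique_amount < 0):
                raise ValueError("negative unique amounts")

    @property
    def total_amount(self) -> np.ndarray:
        """n * unique_amount per row."""
        return self.copy_number * self.unique_amount

    @property
    def genome_size(self) -> float:
        """Sum of n * a_n over rows, in bp-equivalents."""
        return float(self.total_amount.sum())

    @property
    def unique_total(self) -> float:
        """Sum of a_n over rows: distinct k-mer total."""
        return float(self.unique_amount.sum())

    def unique_at(self, n: int) -> float:
        idx = np.nonzero(self.copy_number == n)[0]
        return float(self.unique_amount[idx[0]]) if idx.size else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "copy_number": self.copy_number,
                "unique_bp": self.unique_amount,
                "total_bp": self.total_amount,
            }
        )


def count_kmers(sequences: Iterable[str | bytes], k: int = 21) -> KmerCountTable:
    """Count canonical k-mers over every valid window of the input.

    Windows containing any non-ACGT symbol are skipped; sequences shorter
    than k contribute nothing.  Input is case-folded.
    """
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError("k must be a positive integer")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")

    # concatenate with a sentinel between sequences so no window spans two
    chunks: list[np.ndarray] = []
    sep = np.array([4], dtype=np.uint8)
    pending: list[np.ndarray] = []
    pending_size = 0
    CHUNK = 1 << 23  # ~8M bases per canonicalisation pass

    def flush() -> None:
        nonlocal pending, pending_size
        if pending:
            codes = np.concatenate(pending)
            got = _canonical_codes(codes, k)
            if got.size:
                chunks.append(got)
            pending = []
            pending_size = 0

    for seq in sequences:
        arr = encode_bases(seq)
        if arr.size < k:
            continue
        pending.append(arr)
        pending.append(sep)
        pending_size += arr.size + 1
        if pending_size >= CHUNK:
            flush()
    flush()

    if not chunks:
        return KmerCountTable(k=k)
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerCountTable(k=k, codes=codes, counts=counts.astype(np.int64))


def build_spectrum(table: KmerCountTable) -> KmerSpectrum:
    """Histogram a count table into an abundance spectrum."""
    if len(table) == 0:
        return KmerSpectrum(np.empty(0, np.int64), np.empty(0, np.int64), table.k)
    x, z = np.unique(table.counts, return_counts=True)
    return KmerSpectrum(x, z.astype(np.int64), table.k)


def genome_copy_table(sequences: Iterable[str | bytes], k: int = 21) -> RepeatProfile:
    """Exact per-copy-number tabulation of an assembled genome.

    Row n holds the number of distinct canonical k-mers occurring exactly
    n times across the given contigs.
    """
    spectrum = build_spectrum(count_kmers(sequences, k))
    return RepeatProfile(spectrum.abundance.copy(), spectrum.count.astype(float))
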