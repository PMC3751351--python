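"""Spectrum diagnostics and copy-number tables for display.

These transformations are presentation-layer only: the coverage-weighted
spectrum makes repeat peaks visible on a plot but is never used in
fitting, and the rank-order statistics summarise a read set's k-mer
composition in a way that is stable under changes of sampling depth.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .counting import KmerCountTable, KmerSpectrum, RepeatProfile

__all__ = [
    "transformed_spectrum",
    "rank_order_stats",
    "report_table",
    "DEFAULT_BINS",
]

# display bins: copy numbers 1..10 individually, then two ranges
DEFAULT_BINS: tuple[tuple[int, int], ...] = tuple(
    [(n, n) for n in range(1, 11)] + [(11, 20), (21, 79)]
)


def transformed_spectrum(spectrum: KmerSpectrum) -> np.ndarray:
    """Coverage-weighted spectrum: pairs (x, x * z_x).

    The second column sums to the total number of k-mer instances, so the
    transformed curve shows where the sequenced bases went; it plays no
    role in model fitting.
    """
    return np.column_stack(
        (spectrum.abundance, spectrum.abundance * spectrum.count)
    ).astype(np.int64)


def rank_order_stats(source: KmerCountTable | KmerSpectrum):
    """Rank-ordered k-mer abundances and the cumulative data fraction.

    Returns (abundances sorted descending, cumulative fraction of all
    k-mer instances consumed by the top-r k-mers).  The cumulative series
    is non-decreasing and ends at 1.
    """
    if isinstance(source, KmerSpectrum):
        if len(source) == 0:
            raise ValueError("empty spectrum")
        abundances = np.repeat(source.abundance[::-1], source.count[::-1])
    else:
        if len(source) == 0:
            raise ValueError("empty count table")
        abundances = np.sort(source.counts)[::-1]
    total = abundances.sum()
    return abundances, np.cumsum(abundances) / total


def _bin_profile(profile: RepeatProfile, bins) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels: list[str] = []
    uniq: list[float] = []
    tot: list[float] = []
    covered = np.zeros(profile.copy_number.size, dtype=bool)
    for lo, hi in bins:
        sel = (profile.copy_number >= lo) & (profile.copy_number <= hi)
        covered |= sel
        labels.append(f"{lo}x" if lo == hi else f"{lo}x-{hi}x")
        uniq.append(float(profile.unique_amount[sel].sum()))
        tot.append(float(profile.total_amount[sel].sum()))
    if np.any(~covered):
        rest = profile.copy_number[~covered]
        labels.append(f">{int(rest.min()) - 1}x")
        uniq.append(float(profile.unique_amount[~covered].sum()))
        tot.append(float(profile.total_amount[~covered].sum()))
    return labels, np.asarray(uniq), np.asarray(tot)


def report_table(
    profiles: RepeatProfile | Sequence[RepeatProfile],
    bins=DEFAULT_BINS,
    names: Sequence[str] | None = None,
) -> str:
    """Side-by-side binned copy-number table as TSV, with cumulative totals.

    Each profile contributes a ``unique``/``total`` column pair; rows are
    the requested copy-number bins (any copy numbers beyond them are
    gathered into a trailing overflow bin) plus a final cumulative row.
    """
    if isinstance(profiles, RepeatProfile):
        profiles = [profiles]
    if names is None:
        names = [f"profile_{i + 1}" for i in range(len(profiles))]
    if len(names) != len(profiles):
        raise ValueError("one name per profile required")

    label_order: list[str] = []
    data: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    for name, prof in zip(names, profiles):
        labels, uniq, tot = _bin_profile(prof, bins)
        for label in labels:
            if label not in label_order:
                label_order.append(label)
        data[f"{name}_unique"] = dict(zip(labels, uniq))
        data[f"{name}_total"] = dict(zip(labels, tot))
        totals[f"{name}_unique"] = prof.unique_total
        totals[f"{name}_total"] = prof.genome_size

    frame = pd.DataFrame(data).reindex(label_order).fillna(0.0)
    frame.loc["cumulative"] = [totals[col] for col in frame.columns]
    frame.index.name = "copy_number"
    return frame.to_csv(sep="\t", float_format="%.0f")
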