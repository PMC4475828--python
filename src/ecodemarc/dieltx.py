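"""Diel transcript assignment and two-stage normalization.

Transcript (cDNA) reads are assigned to putative ecotypes by exact match
over a shared trimmed window, or recruited to lineage gene sets by a
mismatch-bounded ungapped scan. Counts are then normalized per timepoint
(share of the timepoint's total) and per category (divided by the
geometric mean of the shares across timepoints), so a value of 1 means
"at this hour, average share for this population".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import as_array, reverse_complement


@dataclass
class DielSeries:
    """Category x timepoint transcript counts with a missing-timepoint mask."""

    counts: pd.DataFrame  # categories x timepoints (numeric columns)
    missing: list = field(default_factory=list)
    ambiguous: pd.Series | None = None  # per timepoint
    unassigned: pd.Series | None = None
    zero_activity: list = field(default_factory=list)

    def totals(self) -> pd.Series:
        tot = self.counts.sum(axis=0)
        if self.unassigned is not None:
            tot = tot + self.unassigned.reindex(tot.index, fill_value=0)
        return tot


@dataclass
class NormalizedSeries:
    values: pd.DataFrame  # category x timepoint, positive reals
    shares: pd.DataFrame
    pseudocount: float


def match_transcripts(
    reads_by_timepoint: Mapping[float, Sequence[str]],
    pe_windows: Mapping[str, Sequence[str]],
    missing: Sequence[float] = (),
) -> DielSeries:
    """Exact-match assignment of windowed cDNA reads to PEs.

    A read counts toward a PE iff it is identical to one of that PE's
    variant sequences over the window; reads whose sequence occurs in the
    window sets of more than one PE (possible after trimming) are discarded
    as ambiguous and tallied separately, as are unmatched reads.
    """
    window_lens = {len(w) for ws in pe_windows.values() for w in ws}
    if len(window_lens) > 1:
        raise ValueError(f"inconsistent window lengths: {sorted(window_lens)}")
    lookup: dict[str, str] = {}
    ambiguous_windows: set[str] = set()
    for pe, windows in pe_windows.items():
        for w in windows:
            if w in lookup and lookup[w] != pe:
                ambiguous_windows.add(w)
            else:
                lookup[w] = pe
    timepoints = sorted(reads_by_timepoint)
    counts = pd.DataFrame(0, index=sorted(pe_windows), columns=timepoints,
                          dtype=int)
    amb = pd.Series(0, index=timepoints, dtype=int)
    unas = pd.Series(0, index=timepoints, dtype=int)
    for t in timepoints:
        for read in reads_by_timepoint[t]:
            if window_lens and len(read) != next(iter(window_lens)):
                raise ValueError("read length does not match window length")
            if read in ambiguous_windows:
                amb[t] += 1
            elif read in lookup:
                counts.loc[lookup[read], t] += 1
            else:
                unas[t] += 1
    return DielSeries(counts=counts, missing=sorted(missing), ambiguous=amb,
                      unassigned=unas)


def _best_hamming(read: str, gene: str) -> int:
    """Minimum Hamming distance of `read` over all ungapped offsets of `gene`."""
    r = as_array(read)
    g = as_array(gene)
    n, m = len(g), len(r)
    if m > n:
        return m
    best = m
    for off in range(n - m + 1):
        d = int((g[off:off + m] != r).sum())
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


def recruit_reads(
    reads_by_timepoint: Mapping[float, Sequence[str]],
    genes_by_lineage: Mapping[str, Sequence[str]],
    max_mismatch: int = 5,
) -> DielSeries:
    """Mismatch-bounded ungapped recruitment of short reads to lineages.

    Each read is scanned against every gene of every lineage on both
    strands; it is recruited to the lineage of its best-matching gene if
    that best Hamming distance is <= max_mismatch. Reads tying across
    lineages are discarded and tallied as ambiguous.
    """
    timepoints = sorted(reads_by_timepoint)
    lineages = sorted(genes_by_lineage)
    counts = pd.DataFrame(0, index=lineages, columns=timepoints, dtype=int)
    amb = pd.Series(0, index=timepoints, dtype=int)
    unas = pd.Series(0, index=timepoints, dtype=int)
    for t in timepoints:
        for read in reads_by_timepoint[t]:
            rc = reverse_complement(read)
            best_by_lineage = {}
            for lin in lineages:
                d = min(
                    min(_best_hamming(read, g), _best_hamming(rc, g))
                    for g in genes_by_lineage[lin]
                )
                best_by_lineage[lin] = d
            dmin = min(best_by_lineage.values())
            if dmin > max_mismatch:
                unas[t] += 1
                continue
            winners = [l for l, d in best_by_lineage.items() if d == dmin]
            if len(winners) > 1:
                amb[t] += 1
            else:
                counts.loc[winners[0], t] += 1
    return DielSeries(counts=counts, ambiguous=amb, unassigned=unas)


def normalize_diel(series: DielSeries, pseudocount: float = 0.5,
                   include_unassigned: bool = False) -> NormalizedSeries:
    """Two-stage normalization: per-timepoint share, then geometric mean.

    value(c, t) = share(c, t) / geomean_t share(c, .), where
    share(c, t) = count(c, t) / total(t) with zero counts replaced by
    ``pseudocount`` first, so the per-category geometric mean of the
    output over non-missing timepoints is exactly 1. By default the
    denominator counts assigned reads only.
    """
    counts = series.counts.astype(float)
    cols = [c for c in counts.columns if c not in set(series.missing)]
    counts = counts[cols]
    if counts.shape[1] == 0:
        raise ValueError("all timepoints missing")
    totals = counts.sum(axis=0)
    if include_unassigned and series.unassigned is not None:
        totals = totals + series.unassigned.reindex(cols, fill_value=0)
    if (totals <= 0).any():
        bad = [c for c in cols if totals[c] <= 0]
        raise ValueError(f"zero total at timepoints {bad}")
    adj = counts.where(counts > 0, pseudocount)
    shares = adj.div(totals, axis=1)
    log_gm = np.log(shares).mean(axis=1)
    values = shares.div(np.exp(log_gm), axis=0)
    return NormalizedSeries(values=values, shares=shares,
                            pseudocount=pseudocount)
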