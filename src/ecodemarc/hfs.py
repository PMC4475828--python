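"""Dereplication into unique variants, HFS selection, lineage assignment.

After cleaning, all reads share the reference frame and length, so
dereplication is exact string identity and lineage assignment is
positional (alignment-free) identity against genomic homologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import identity_fraction

LINEAGE_A = "A"
LINEAGE_BPRIME = "B'"
LINEAGE_APRIME = "A'"
UNCLASSIFIED = "unclassified"


@dataclass
class VariantTable:
    """Counts of unique cleaned sequences per sample.

    Variant ids are v0001, v0002, ... ordered by descending total count,
    ties broken lexicographically by sequence.
    """

    sequences: dict[str, str]          # variant id -> sequence
    counts: pd.DataFrame               # variant id x sample id

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_per_sample(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "sequence", pd.Series(self.sequences))
        out.insert(1, "total", self.totals)
        return out


@dataclass
class HighFrequencySet:
    threshold: int
    members: list[str]                 # variant ids with total > threshold


@dataclass
class LineageLabel:
    value: str
    identity_to_best_ref: float        # percentage


def dereplicate_and_count(
    reads_by_sample: Mapping[str, Sequence[str]]
) -> VariantTable:
    """Exact dereplication with per-sample occurrence counts.

    Empty samples keep a zero column. All reads must share one length.
    """
    lengths = {len(s) for reads in reads_by_sample.values() for s in reads}
    if len(lengths) > 1:
        raise ValueError(f"reads of unequal length: {sorted(lengths)}")
    samples = list(reads_by_sample)
    tallies: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for seq in reads:
            tallies.setdefault(seq, dict.fromkeys([], 0))
            tallies[seq][sample] = tallies[seq].get(sample, 0) + 1
    seqs = list(tallies)
    totals = {s: sum(tallies[s].values()) for s in seqs}
    seqs.sort(key=lambda s: (-totals[s], s))
    ids = [f"v{i + 1:04d}" for i in range(len(seqs))]
    counts = pd.DataFrame(
        [[tallies[s].get(sample, 0) for sample in samples] for s in seqs],
        index=ids, columns=samples, dtype=int)
    return VariantTable(sequences=dict(zip(ids, seqs)), counts=counts)


def select_hfs(table: VariantTable, threshold: int = 50) -> HighFrequencySet:
    """Variants with strictly more than `threshold` identical reads pooled
    across all samples (DNA and cDNA pooled by default)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = table.totals
    members = [v for v in table.counts.index if totals[v] > threshold]
    return HighFrequencySet(threshold=threshold, members=members)


def assign_lineage(
    variant: str,
    refs: Mapping[str, object],
    identity_threshold: float = 0.95,
    aprime_floor: float | None = None,
) -> LineageLabel:
    """Classify a reference-framed variant to the A, B' or A' lineage.

    refs maps "A" and "B'" to single genomic homolog sequences and "A'"
    to a set of metagenomic reference sequences. The variant is labelled
    A or B' when that homolog is its best match at >= 95% positional
    identity; it is labelled A' when its best match overall lies in the
    A' reference set (no identity floor unless ``aprime_floor`` is set);
    otherwise it is unclassified.
    """
    for key in (LINEAGE_A, LINEAGE_BPRIME, LINEAGE_APRIME):
        if key not in refs:
            raise ValueError(f"missing reference set {key!r}")
    id_a = identity_fraction(variant, refs[LINEAGE_A])
    id_b = identity_fraction(variant, refs[LINEAGE_BPRIME])
    aprime = list(refs[LINEAGE_APRIME])
    id_ap = max((identity_fraction(variant, r) for r in aprime), default=-1.0)
    best = max(id_a, id_b, id_ap)
    if id_ap == best and aprime and (aprime_floor is None or id_ap >= aprime_floor):
        return LineageLabel(LINEAGE_APRIME, 100.0 * id_ap)
    if id_a >= id_b and id_a >= identity_threshold:
        return LineageLabel(LINEAGE_A, 100.0 * id_a)
    if id_b > id_a and id_b >= identity_threshold:
        return LineageLabel(LINEAGE_BPRIME, 100.0 * id_b)
    return LineageLabel(UNCLASSIFIED, 100.0 * best)
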