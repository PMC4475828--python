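"""LFS assignment to PEs and per-sample PE relative abundances.

Low-frequency sequences (LFS) are placed by nearest high-frequency
sequence (HFS) under reference-framed Hamming distance, leaf-to-leaf:
if the nearest and second-nearest HFS belong to the same PE the LFS is
inside that PE's clade, otherwise it is tentatively assigned to the PE
of its nearest HFS, with distance ties broken toward the PE of the
globally more abundant HFS. The percentage contribution of a PE in a
sample is (PE sequences in sample / all sequences in sample) x 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import hamming
from .hfs import HighFrequencySet, VariantTable

HFS_MEMBER = "HFS-member"
LFS_WITHIN_CLADE = "LFS-within-clade"
LFS_NEAREST_PE = "LFS-nearest-PE"


@dataclass
class PEAssignment:
    mapping: dict[str, tuple[str, str]]  # variant id -> (PE id, basis)

    def pe_of(self, variant: str) -> str:
        return self.mapping[variant][0]


def assign_lfs(
    lfs_seq: str,
    hfs_seqs: Mapping[str, str],
    partition: Mapping[str, str],
    hfs_totals: Mapping[str, int],
) -> tuple[str, str]:
    """Assign one LFS to a PE by nearest-HFS distance.

    Returns (PE id, basis). Deterministic: among equidistant nearest HFS
    the one with the larger global count wins (then lexicographic id).
    """
    if not hfs_seqs:
        raise ValueError("no HFS to assign against")
    dists = {h: hamming(lfs_seq, s) for h, s in hfs_seqs.items()}
    ranked = sorted(dists, key=lambda h: (dists[h], -hfs_totals.get(h, 0), h))
    nearest = ranked[0]
    d0 = dists[nearest]
    tied = [h for h in ranked if dists[h] == d0]
    pes_tied = {partition[h] for h in tied}
    if len(pes_tied) > 1:
        return partition[nearest], LFS_NEAREST_PE
    if len(ranked) >= 2 and partition[ranked[1]] == partition[nearest]:
        return partition[nearest], LFS_WITHIN_CLADE
    if len(ranked) == 1:
        return partition[nearest], LFS_NEAREST_PE
    return partition[nearest], LFS_NEAREST_PE


def build_assignment(
    table: VariantTable,
    hfs_set: HighFrequencySet,
    partition: Mapping[str, str],
) -> PEAssignment:
    """Assign every variant of the table a PE: HFS by membership in the
    demarcation partition, LFS by nearest HFS."""
    hfs_seqs = {h: table.sequences[h] for h in hfs_set.members}
    totals = table.totals
    hfs_totals = {h: int(totals[h]) for h in hfs_set.members}
    mapping: dict[str, tuple[str, str]] = {}
    for v in table.counts.index:
        if v in hfs_seqs:
            mapping[v] = (partition[v], HFS_MEMBER)
        else:
            mapping[v] = assign_lfs(table.sequences[v], hfs_seqs, partition,
                                    hfs_totals)
    return PEAssignment(mapping)


@dataclass
class AbundanceProfile:
    """Long-format PE x sample percentages, decomposed into components."""

    frame: pd.DataFrame  # columns: pe, sample, total_pct, dominant_pct,
    #                               hfs_pct, lfs_pct

    def wide(self, value: str = "total_pct") -> pd.DataFrame:
        return self.frame.pivot(index="pe", columns="sample", values=value)


def pe_abundance(table: VariantTable, assignment: PEAssignment
                 ) -> AbundanceProfile:
    """Percentage of each PE in each sample, with the dominant-variant,
    other-HFS and pooled-LFS components.

    The dominant variant of a PE is its highest-total HFS member.
    Zero-total samples yield missing percentages with a warning.
    """
    missing = set(table.counts.index) - set(assignment.mapping)
    if missing:
        raise ValueError(f"variants without assignment: {sorted(missing)[:5]}")
    totals_per_sample = table.total_per_sample()
    variant_totals = table.totals
    pes = sorted({pe for pe, _ in assignment.mapping.values()})
    rows = []
    for pe in pes:
        members = [v for v, (p, _) in assignment.mapping.items() if p == pe]
        hfs_members = [v for v in members
                       if assignment.mapping[v][1] == HFS_MEMBER]
        lfs_members = [v for v in members
                       if assignment.mapping[v][1] != HFS_MEMBER]
        dominant = (max(hfs_members, key=lambda v: (variant_totals[v], v))
                    if hfs_members else None)
        for sample in table.counts.columns:
            denom = totals_per_sample[sample]
            if denom == 0:
                warnings.warn(f"sample {sample} has zero total; "
                              "percentages undefined")
                rows.append((pe, sample, np.nan, np.nan, np.nan, np.nan))
                continue
            total = table.counts.loc[members, sample].sum()
            dom = table.counts.loc[dominant, sample] if dominant else 0
            hfs_other = (table.counts.loc[hfs_members, sample].sum() - dom)
            lfs = table.counts.loc[lfs_members, sample].sum()
            rows.append((pe, sample, 100.0 * total / denom,
                         100.0 * dom / denom, 100.0 * hfs_other / denom,
                         100.0 * lfs / denom))
    frame = pd.DataFrame(rows, columns=["pe", "sample", "total_pct",
                                        "dominant_pct", "hfs_pct", "lfs_pct"])
    return AbundanceProfile(frame)


def summarize_replicates(profile: AbundanceProfile,
                         replicate_of: Mapping[str, str]) -> pd.DataFrame:
    """Collapse replicate samples to mean with range (min/max) per PE."""
    f = profile.frame.copy()
    f["group"] = f["sample"].map(replicate_of)
    g = f.groupby(["pe", "group"])["total_pct"]
    return g.agg(mean="mean", low="min", high="max").reset_index()
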