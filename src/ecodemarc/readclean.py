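"""Homopolymer frameshift correction against an in-frame consensus reference.

Pyrosequencing miscalls homopolymer run lengths, producing insertions and
deletions that frameshift a protein-coding amplicon. Each raw read is
aligned globally, in all four orientations, to an in-frame consensus
reference; read bases that open a gap in the reference are excised as
erroneous homopolymer copies, the read is trimmed to the reference span,
and reads that still lack reference positions (deletions) are discarded.

Alignment is deterministic global pairwise with affine gap penalties
(defaults match=+2, mismatch=-3, open=-5, extend=-2) against the fixed
reference, which is what the excision rule consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import Align

from ._util import IUPAC, complement, reverse_complement

ORIENTATIONS = ("forward", "reverse-complement", "complement", "reverse")

DEFAULT_SCORING = (2.0, -3.0, -5.0, -2.0)  # match, mismatch, open, extend


@dataclass
class ConsensusReference:
    sequence: str
    frame_offset: int = 0

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty reference")
        if "-" in self.sequence:
            raise ValueError("reference must contain no gap characters")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


@dataclass
class CleanedRead:
    id: str
    sequence: str
    orientation_used: str
    n_excised: int


@dataclass
class Rejection:
    id: str
    reason: str  # "gap" or "quality"


@dataclass
class CleaningReport:
    n_input: int = 0
    n_passed: int = 0
    n_rejected_gap: int = 0
    n_rejected_quality: int = 0

    def check(self) -> None:
        assert self.n_input == (self.n_passed + self.n_rejected_gap
                                + self.n_rejected_quality)


def _aligner(scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    return Align.PairwiseAligner(
        mode="global", match_score=match, mismatch_score=mismatch,
        open_gap_score=gap_open, extend_gap_score=gap_extend)


def orient(read: str, orientation: str) -> str:
    if orientation == "forward":
        return read
    if orientation == "reverse-complement":
        return reverse_complement(read)
    if orientation == "complement":
        return complement(read)
    if orientation == "reverse":
        return read[::-1]
    raise ValueError(f"unknown orientation {orientation!r}")


def best_orientation_alignment(read: str, reference: ConsensusReference,
                               scoring=DEFAULT_SCORING):
    """Highest-scoring global alignment among the four orientations.

    Ties are broken by fixed priority
    forward > reverse-complement > complement > reverse.
    Returns (Bio.Align.Alignment, orientation).
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    if not set(read) <= IUPAC:
        raise ValueError("read contains non-IUPAC characters")
    aligner = _aligner(scoring)
    best = None
    for orientation in ORIENTATIONS:
        candidate = orient(read, orientation)
        score = aligner.score(reference.sequence, candidate)
        if best is None or score > best[0]:
            best = (score, orientation, candidate)
    score, orientation, candidate = best
    alignment = aligner.align(reference.sequence, candidate)[0]
    return alignment, orientation


def excise_frameshift_bases(alignment, orientation: str = "forward",
                            read_id: str = "read") -> CleanedRead | Rejection:
    """Excise read bases that gap the reference; reject residual gaps.

    Every read base that falls outside the reference frame -- aligned to
    a reference gap, or overhanging the reference span -- is removed and
    counted in n_excised. If any reference position is left without a
    read base (a deletion relative to the reference frame) the read is
    rejected with reason "gap".
    """
    ref_len = len(alignment.target)
    blocks = alignment.aligned  # [[target blocks], [query blocks]]
    tb, qb = blocks[0], blocks[1]
    covered = sum(int(e - s) for s, e in tb)
    if covered < ref_len:
        return Rejection(read_id, "gap")
    query = str(alignment.query)
    pieces = [query[qs:qe] for qs, qe in qb]
    cleaned = "".join(pieces)
    assert len(cleaned) == ref_len
    n_excised = len(query) - covered
    return CleanedRead(read_id, cleaned, orientation, int(n_excised))


def clean_read(read_id: str, read: str, reference: ConsensusReference,
               scoring=DEFAULT_SCORING, min_length_fraction: float = 0.5
               ) -> CleanedRead | Rejection:
    """Clean a single read; quality-reject short or non-IUPAC reads."""
    if len(read) < min_length_fraction * len(reference.sequence):
        return Rejection(read_id, "quality")
    try:
        alignment, orientation = best_orientation_alignment(
            read, reference, scoring)
    except ValueError:
        return Rejection(read_id, "quality")
    return excise_frameshift_bases(alignment, orientation, read_id)


def clean_reads(reads: Iterable[tuple[str, str]],
                reference: ConsensusReference,
                scoring=DEFAULT_SCORING,
                min_length_fraction: float = 0.5,
                cdna_window: tuple[int, int] | None = None
                ) -> tuple[list[CleanedRead], list[Rejection], CleaningReport]:
    """Stream reads through orientation selection, excision and trimming.

    cdna_window (start, end), when given, trims every cleaned read to that
    column window of the reference frame (the cDNA analysis mode).
    """
    report = CleaningReport()
    passed: list[CleanedRead] = []
    rejected: list[Rejection] = []
    for read_id, seq in reads:
        report.n_input += 1
        result = clean_read(read_id, seq, reference, scoring,
                            min_length_fraction)
        if isinstance(result, CleanedRead):
            if cdna_window is not None:
                start, end = cdna_window
                result = CleanedRead(result.id,
                                     result.sequence[start:end],
                                     result.orientation_used,
                                     result.n_excised)
            passed.append(result)
            report.n_passed += 1
        elif result.reason == "gap":
            rejected.append(result)
            report.n_rejected_gap += 1
        else:
            rejected.append(result)
            report.n_rejected_quality += 1
    report.check()
    return passed, rejected, report
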