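"""Shared helpers: sequence arithmetic, seeding, FASTA round-trips."""

from __future__ import annotations

import zlib
from typing import Iterable, Iterator, Sequence

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVNacgtrykmswbdhvn",
                            "TGCAYRMKSWVHDBNtgcayrmkswvhdbn")

IUPAC = set("ACGTURYKMSWBDHVN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def identity_fraction(a: str, b: str) -> float:
    """Positional identity of two reference-framed, equal-length sequences."""
    return 1.0 - hamming(a, b) / len(a)


def derive_seed(master: int, *context) -> int:
    """Stable per-stage/per-object seed below 2**31 derived from a master seed.

    Context items (strings/ints) are hashed with crc32 so the same logical
    unit always receives the same stream regardless of execution order.
    """
    payload = repr((int(master),) + tuple(context)).encode()
    return zlib.crc32(payload) % (2**31)


def rng_for(master: int, *context) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *context))


def read_fasta(path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of identical bases as (start, length), length >= 1."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


def as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Substitute each position with a uniformly chosen *different* base."""
    out = list(seq)
    for p in positions:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)
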