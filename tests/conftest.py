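"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ecodemarc import synth
from ecodemarc._util import derive_seed, hamming


def make_reference(seed: int, length: int = 324) -> str:
    rng = np.random.default_rng(derive_seed(seed, "test-reference"))
    return "".join(rng.choice(list("ACGT"), size=length))


def planted_ecotype_sequences(seed: int, n_ecotypes: int = 3,
                              n_hfs: int = 3, n_lfs: int = 0,
                              separation: float = 10.0,
                              length: int = 324):
    """Well-separated ecotype variant clouds keyed '<eco>_h<i>'."""
    reference = make_reference(seed, length)
    specs = [
        synth.EcotypeSpec(
            id=f"eco{i}", niche_center=(60.0 + 3.0 * i, 100.0 + 120.0 * i),
            niche_breadth=(2.0, 150.0), n_hfs=n_hfs, n_lfs=n_lfs)
        for i in range(n_ecotypes)
    ]
    haps = synth.generate_community_haplotypes(
        specs, reference, seed, hfs_distance=2, separation_factor=separation)
    seqs = {f"{eco}_h{i}": h
            for eco, hlist in haps.items()
            for i, (h, _) in enumerate(hlist)}
    return reference, specs, haps, seqs


def best_deletion_oracle(read: str, reference: str):
    """Exhaustive oracle for frameshift excision on short reads.

    Enumerates every way of deleting len(read) - len(reference) bases
    from the read and returns (min Hamming distance to the reference,
    set of sequences achieving it). Exponential -- for toy pairs only.
    """
    k = len(read) - len(reference)
    if k < 0:
        return None, set()
    best = len(reference) + 1
    winners: set[str] = set()
    for keep in itertools.combinations(range(len(read)), len(reference)):
        cand = "".join(read[i] for i in keep)
        d = hamming(cand, reference)
        if d < best:
            best, winners = d, {cand}
        elif d == best:
            winners.add(cand)
    return best, winners


@pytest.fixture(scope="session")
def reference324() -> str:
    return make_reference(11)
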