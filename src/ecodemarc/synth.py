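"""Synthetic communities, haplotypes, reads and diel transcript series.

This module manufactures data with the statistical structure the downstream
pipeline assumes: several ecotypes, each a tight cloud of sequence variants
around a dominant haplotype, distributed over a temperature x depth habitat
grid with Gaussian niches, sampled multinomially and corrupted by
pyrosequencing-style homopolymer insertion/deletion errors.

Substitution-only haplotypes are generated (no true biological indels), so
that frame-based read cleaning has unambiguous ground truth: every indel in
a read is, by construction, a sequencing artifact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import homopolymer_runs, mutate, rng_for, write_fasta
from .dieltx import DielSeries

DOMINANT = "dominant"
HFS = "HFS"
LFS = "LFS"


@dataclass
class EcotypeSpec:
    """One planted ecotype: its niche and its variant structure.

    niche_center is (temperature degC, depth um); niche_breadth the
    corresponding Gaussian sigmas. n_hfs counts high-frequency variants
    including the dominant one; n_lfs counts low-frequency satellites.
    """

    id: str
    niche_center: tuple[float, float]
    niche_breadth: tuple[float, float]
    weight: float = 1.0
    n_hfs: int = 1
    n_lfs: int = 0
    dominant_haplotype: str | None = None

    def __post_init__(self):
        if self.niche_breadth[0] <= 0 or self.niche_breadth[1] <= 0:
            raise ValueError("niche breadths must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.n_hfs < 1 or self.n_lfs < 0:
            raise ValueError("need n_hfs >= 1 and n_lfs >= 0")


@dataclass
class ErrorModel:
    """Homopolymer indel error model.

    Per maximal run of identical bases of length L, one extra copy of the
    run base is inserted with probability p_ins * L**run_length_exponent,
    or one base deleted with p_del * L**run_length_exponent; at most one
    event per run, so the per-read expectation stays in closed form.
    """

    p_ins: float = 0.0
    p_del: float = 0.0
    run_length_exponent: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.p_ins < 1 and 0 <= self.p_del < 1):
            raise ValueError("error probabilities must lie in [0, 1)")

    def corrupt(self, seq: str, rng: np.random.Generator) -> tuple[str, int, int]:
        """Return (corrupted read, n_insertions, n_deletions)."""
        if self.p_ins == 0 and self.p_del == 0:
            return seq, 0, 0
        out = []
        n_ins = n_del = 0
        for start, length in homopolymer_runs(seq):
            run = seq[start:start + length]
            scale = length ** self.run_length_exponent
            u = rng.random()
            if u < self.p_ins * scale:
                out.append(run + run[0])
                n_ins += 1
            elif u < (self.p_ins + self.p_del) * scale:
                out.append(run[:-1])
                n_del += 1
            else:
                out.append(run)
        return "".join(out), n_ins, n_del


@dataclass
class SampleMeta:
    sample_id: str
    temperature: float
    depth: float
    timepoint: str = "T0"
    condition: str = "none"


@dataclass
class CommunityGrid:
    """True relative abundances of each ecotype in each sample."""

    samples: list[SampleMeta]
    abundance: pd.DataFrame  # ecotype x sample, columns ordered as samples

    def __post_init__(self):
        sums = self.abundance.sum(axis=0).to_numpy()
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundance")
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-sample abundances must sum to 1")

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).rename(columns={"temperature": "temperature_C", "depth": "depth_um"})


def generate_haplotypes(
    spec: EcotypeSpec,
    reference: str,
    seed: int,
    hfs_distance: int = 2,
    lfs_distance: int = 1,
) -> list[tuple[str, str]]:
    """Generate the variant cloud of one ecotype.

    Returns [(haplotype, class)] with exactly one dominant, n_hfs - 1
    high-frequency and n_lfs low-frequency haplotypes. Variants carry
    substitutions at randomly placed, mutually disjoint positions, so
    non-dominant HFS sit at Hamming distance ``hfs_distance`` from the
    dominant and 2 * hfs_distance from each other, and each LFS differs
    from its parent variant by ``lfs_distance`` substitutions.
    """
    if not reference:
        raise ValueError("empty reference")
    dominant = spec.dominant_haplotype or reference
    if len(dominant) != len(reference):
        raise ValueError("dominant haplotype length must equal reference length")
    rng = rng_for(seed, "haplotypes", spec.id)
    n_sites = (spec.n_hfs - 1) * hfs_distance + spec.n_lfs * lfs_distance
    if n_sites > len(reference):
        raise ValueError(
            f"reference of length {len(reference)} too short for "
            f"{n_sites} distinct mutation sites"
        )
    sites = rng.choice(len(reference), size=n_sites, replace=False)
    out: list[tuple[str, str]] = [(dominant, DOMINANT)]
    cursor = 0
    hfs_pool = [dominant]
    for _ in range(spec.n_hfs - 1):
        pos = sites[cursor:cursor + hfs_distance]
        cursor += hfs_distance
        hap = mutate(dominant, pos, rng)
        out.append((hap, HFS))
        hfs_pool.append(hap)
    for _ in range(spec.n_lfs):
        pos = sites[cursor:cursor + lfs_distance]
        cursor += lfs_distance
        parent = hfs_pool[rng.integers(len(hfs_pool))]
        out.append((mutate(parent, pos, rng), LFS))
    return out


def generate_community_haplotypes(
    specs: Sequence[EcotypeSpec],
    reference: str,
    seed: int,
    hfs_distance: int = 2,
    lfs_distance: int = 1,
    separation_factor: float = 5.0,
) -> dict[str, list[tuple[str, str]]]:
    """Plant dominants for every ecotype, then grow each variant cloud.

    Each ecotype's dominant is the reference mutated at an exclusive block
    of sites sized so that the minimum between-ecotype Hamming distance
    exceeds the maximum within-ecotype distance by at least
    ``separation_factor``, even when variant substitutions land inside
    another ecotype's block; the guarantee is re-checked after generation
    and violations raise.
    """
    rng = rng_for(seed, "dominants")
    has_lfs = any(s.n_lfs > 0 for s in specs)
    within_max = 2 * (hfs_distance + (lfs_distance if has_lfs else 0))
    per_hap = hfs_distance + (lfs_distance if has_lfs else 0)
    k = int(np.ceil((separation_factor * within_max + 2 * per_hap) / 2.0))
    need = k * len(specs)
    if need > len(reference):
        raise ValueError("reference too short for requested ecotype separation")
    blocks = rng.choice(len(reference), size=need, replace=False)
    haplotypes: dict[str, list[tuple[str, str]]] = {}
    for i, spec in enumerate(specs):
        if spec.dominant_haplotype is None:
            dom = mutate(reference, blocks[i * k:(i + 1) * k], rng)
            spec = dataclasses.replace(spec, dominant_haplotype=dom)
        haplotypes[spec.id] = generate_haplotypes(
            spec, reference, seed, hfs_distance, lfs_distance
        )
    if len(specs) > 1:
        _check_separation(haplotypes, separation_factor)
    return haplotypes


def _check_separation(haplotypes: Mapping[str, list[tuple[str, str]]],
                      factor: float) -> None:
    from ._util import hamming

    within_max = 1
    for haps in haplotypes.values():
        seqs = [h for h, _ in haps]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                within_max = max(within_max, hamming(seqs[i], seqs[j]))
    ids = list(haplotypes)
    between_min = None
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            for ha, _ in haplotypes[ids[a]]:
                for hb, _ in haplotypes[ids[b]]:
                    d = hamming(ha, hb)
                    between_min = d if between_min is None else min(between_min, d)
    if between_min is not None and between_min < factor * within_max:
        raise ValueError(
            f"ecotype separation violated: between {between_min} < "
            f"{factor} x within {within_max}"
        )


def simulate_community(
    specs: Sequence[EcotypeSpec],
    samples: Sequence[SampleMeta],
    seed: int = 0,
) -> CommunityGrid:
    """Gaussian-product niche model over a (temperature, depth) grid.

    Relative abundance of ecotype i at (T, z) is proportional to
    weight_i * exp(-(T - T_i)^2 / (2 sT^2) - (z - z_i)^2 / (2 sz^2)),
    normalized within each sample.
    """
    if not specs:
        raise ValueError("need at least one ecotype spec")
    if not samples:
        raise ValueError("empty sample grid")
    rows = []
    for spec in specs:
        T0, z0 = spec.niche_center
        sT, sz = spec.niche_breadth
        row = [
            spec.weight
            * np.exp(-((s.temperature - T0) ** 2) / (2 * sT**2)
                     - ((s.depth - z0) ** 2) / (2 * sz**2))
            for s in samples
        ]
        rows.append(row)
    mat = np.asarray(rows, dtype=float)
    col = mat.sum(axis=0)
    if (col == 0).any():
        raise ValueError("a sample received zero density from every ecotype")
    mat /= col
    df = pd.DataFrame(mat, index=[s.id for s in specs],
                      columns=[s.sample_id for s in samples])
    return CommunityGrid(list(samples), df)


@dataclass
class ReadRecord:
    read_id: str
    sample_id: str
    ecotype_id: str
    haplotype_index: int
    haplotype_class: str
    source_haplotype: str
    sequence: str
    n_ins: int
    n_del: int


def _within_ecotype_freqs(haps: list[tuple[str, str]],
                          split: tuple[float, float, float]) -> np.ndarray:
    """Dominant/HFS/LFS frequency split; absent classes fold into dominant."""
    f_dom, f_hfs, f_lfs = split
    classes = [c for _, c in haps]
    n_hfs = classes.count(HFS)
    n_lfs = classes.count(LFS)
    freqs = np.zeros(len(haps))
    dom_share = f_dom + (0 if n_hfs else f_hfs) + (0 if n_lfs else f_lfs)
    for i, c in enumerate(classes):
        if c == DOMINANT:
            freqs[i] = dom_share
        elif c == HFS:
            freqs[i] = f_hfs / n_hfs
        else:
            freqs[i] = f_lfs / n_lfs
    return freqs / freqs.sum()


def simulate_reads(
    community: CommunityGrid,
    haplotypes: Mapping[str, list[tuple[str, str]]],
    depth_per_sample: int,
    error_model: ErrorModel,
    seed: int,
    class_split: tuple[float, float, float] = (0.70, 0.25, 0.05),
) -> list[ReadRecord]:
    """Multinomial read sampling plus homopolymer corruption.

    Reads are drawn multinomially over (ecotype, haplotype): first the
    ecotype per the community's true abundances, then the haplotype with
    the class split (dominant/HFS pool/LFS pool, default 70/25/5). The
    true source haplotype and the number of indel events are recorded.
    """
    if depth_per_sample < 1:
        raise ValueError("depth_per_sample must be >= 1")
    records: list[ReadRecord] = []
    eco_ids = list(community.abundance.index)
    for s in community.samples:
        rng = rng_for(seed, "reads", s.sample_id)
        probs = community.abundance[s.sample_id].to_numpy()
        eco_counts = rng.multinomial(depth_per_sample, probs)
        serial = 0
        for eco, n_eco in zip(eco_ids, eco_counts):
            if n_eco == 0:
                continue
            haps = haplotypes[eco]
            freqs = _within_ecotype_freqs(haps, class_split)
            hap_counts = rng.multinomial(n_eco, freqs)
            for h_idx, n_h in enumerate(hap_counts):
                src, cls = haps[h_idx]
                for _ in range(n_h):
                    seq, n_ins, n_del = error_model.corrupt(src, rng)
                    records.append(ReadRecord(
                        read_id=f"{s.sample_id}|{eco}|h{h_idx}|r{serial}",
                        sample_id=s.sample_id, ecotype_id=eco,
                        haplotype_index=h_idx, haplotype_class=cls,
                        source_haplotype=src, sequence=seq,
                        n_ins=n_ins, n_del=n_del))
                    serial += 1
    return records


def write_reads(records: Sequence[ReadRecord], outdir) -> list[str]:
    """One FASTA per sample; read ids encode sample and true haplotype."""
    import os

    by_sample: dict[str, list[ReadRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    paths = []
    for sample_id in sorted(by_sample):
        path = os.path.join(str(outdir), f"reads_{sample_id}.fasta")
        write_fasta(path, ((r.read_id, r.sequence) for r in by_sample[sample_id]))
        paths.append(path)
    return paths


def truth_table(records: Sequence[ReadRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclass
class DielProfile:
    """Cosine diel activity: baseline + amplitude * cos(2 pi (t - peak)/24)."""

    pe_id: str
    peak_hour: float
    amplitude: float
    baseline: float = 1.0

    def activity(self, hours: np.ndarray) -> np.ndarray:
        a = self.baseline + self.amplitude * np.cos(
            2 * np.pi * (hours - self.peak_hour) / 24.0)
        return np.clip(a, 0.0, None)


def simulate_diel_transcripts(
    profiles: Sequence[DielProfile],
    timepoints: Sequence[float],
    depth: int,
    seed: int,
    missing: Sequence[float] = (),
) -> DielSeries:
    """Multinomial transcript counts per timepoint from relative activities.

    Timepoints in ``missing`` emulate failed sequencing reactions: they are
    carried in the mask and excluded from the output counts.
    """
    rng = rng_for(seed, "diel")
    missing_set = set(missing)
    kept = [t for t in timepoints if t not in missing_set]
    counts = pd.DataFrame(0, index=[p.pe_id for p in profiles],
                          columns=kept, dtype=int)
    flagged: list[float] = []
    for t in kept:
        acts = np.array([p.activity(np.array([t]))[0] for p in profiles])
        total = acts.sum()
        if total == 0:
            flagged.append(t)
            continue
        counts[t] = rng.multinomial(depth, acts / total)
    return DielSeries(counts=counts, missing=sorted(missing_set),
                      zero_activity=flagged)
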