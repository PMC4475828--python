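"""End-to-end orchestration with a single config and a run manifest.

Stages: synthesize (optional) -> clean -> count -> demarcate -> abundance
-> ecostats. All randomness flows from one master seed through per-stage
derived seeds; the manifest records every knob, seed and output checksum,
so a re-run with the same config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import demarc as demarc_mod
from . import ecostats, hfs, readclean, synth
from ._util import derive_seed, write_fasta


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    reference_length: int = 324
    # synthesis
    n_ecotypes: int = 3
    n_hfs: int = 2
    n_lfs: int = 2
    hfs_distance: int = 2
    separation_factor: float = 4.0
    temperatures: tuple[float, ...] = (60.0, 63.0, 65.0, 68.0)
    depths: tuple[float, ...] = (80.0, 240.0, 400.0, 560.0)
    depth_per_sample: int = 400
    p_ins: float = 0.0015
    p_del: float = 0.0008
    run_length_exponent: float = 1.0
    # cleaning
    scoring: tuple[float, float, float, float] = readclean.DEFAULT_SCORING
    # counting
    hfs_threshold: int = 50
    # demarcation
    fit: demarc_mod.FitConfig = field(default_factory=demarc_mod.FitConfig)
    # stats
    n_permutations: int = 999

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit_raw = raw.pop("fit", None)
        cfg = cls(**raw)
        if fit_raw:
            cfg.fit = demarc_mod.FitConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in fit_raw.items()})
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, params: dict, outputs: list[str]) -> None:
        self.stages.append({
            "stage": name,
            "params": params,
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        })

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh,
                      indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _reference(length: int, seed: int) -> str:
    rng = np.random.default_rng(derive_seed(seed, "reference"))
    return "".join(rng.choice(list("ACGT"), size=length))


def run_pipeline(config: RunConfig) -> RunManifest:
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(cfg))
    seed = cfg.seed

    # --- synthesize ------------------------------------------------------
    reference = _reference(cfg.reference_length, seed)
    ref_path = os.path.join(cfg.outdir, "reference.fasta")
    write_fasta(ref_path, [("consensus_reference", reference)])
    specs = []
    t_lo, t_hi = min(cfg.temperatures), max(cfg.temperatures)
    z_lo, z_hi = min(cfg.depths), max(cfg.depths)
    for i in range(cfg.n_ecotypes):
        frac = i / max(cfg.n_ecotypes - 1, 1)
        specs.append(synth.EcotypeSpec(
            id=f"eco{i + 1}",
            niche_center=(t_lo + frac * (t_hi - t_lo),
                          z_lo + frac * (z_hi - z_lo)),
            niche_breadth=(2.0, 150.0),
            n_hfs=cfg.n_hfs, n_lfs=cfg.n_lfs))
    haplotypes = synth.generate_community_haplotypes(
        specs, reference, derive_seed(seed, "haplotypes"),
        hfs_distance=cfg.hfs_distance,
        separation_factor=cfg.separation_factor)
    samples = [synth.SampleMeta(f"T{t:g}_z{z:g}", t, z)
               for t in cfg.temperatures for z in cfg.depths]
    community = synth.simulate_community(specs, samples,
                                         derive_seed(seed, "community"))
    meta_path = os.path.join(cfg.outdir, "metadata.tsv")
    community.metadata_frame().to_csv(meta_path, sep="\t", index=False)
    error_model = synth.ErrorModel(
        p_ins=cfg.p_ins, p_del=cfg.p_del,
        run_length_exponent=cfg.run_length_exponent)
    records = synth.simulate_reads(community, haplotypes,
                                   cfg.depth_per_sample, error_model,
                                   derive_seed(seed, "reads"))
    read_paths = synth.write_reads(records, cfg.outdir)
    truth_path = os.path.join(cfg.outdir, "truth.tsv")
    synth.truth_table(records).to_csv(truth_path, sep="\t", index=False)
    manifest.add("synthesize",
                 {"n_reads": len(records), "seed": seed},
                 [ref_path, meta_path, truth_path] + read_paths)

    # --- clean -----------------------------------------------------------
    ref = readclean.ConsensusReference(reference)
    cleaned_by_sample: dict[str, list[str]] = {}
    report_total = readclean.CleaningReport()
    for s in community.samples:
        sample_reads = [(r.read_id, r.sequence) for r in records
                        if r.sample_id == s.sample_id]
        passed, _, report = readclean.clean_reads(sample_reads, ref,
                                                  cfg.scoring)
        cleaned_by_sample[s.sample_id] = [c.sequence for c in passed]
        report_total.n_input += report.n_input
        report_total.n_passed += report.n_passed
        report_total.n_rejected_gap += report.n_rejected_gap
        report_total.n_rejected_quality += report.n_rejected_quality
    clean_path = os.path.join(cfg.outdir, "cleaning_report.tsv")
    pd.DataFrame([dataclasses.asdict(report_total)]).to_csv(
        clean_path, sep="\t", index=False)
    manifest.add("clean", {"scoring": cfg.scoring}, [clean_path])

    # --- count -----------------------------------------------------------
    table = hfs.dereplicate_and_count(cleaned_by_sample)
    hfs_set = hfs.select_hfs(table, cfg.hfs_threshold)
    table_path = os.path.join(cfg.outdir, "variant_table.tsv")
    table.to_frame().to_csv(table_path, sep="\t")
    hfs_path = os.path.join(cfg.outdir, "hfs.fasta")
    write_fasta(hfs_path, [(v, table.sequences[v]) for v in hfs_set.members])
    manifest.add("count", {"threshold": cfg.hfs_threshold,
                           "n_variants": len(table.sequences),
                           "n_hfs": len(hfs_set.members)},
                 [table_path, hfs_path])

    # --- demarcate -------------------------------------------------------
    hfs_seqs = {v: table.sequences[v] for v in hfs_set.members}
    dm = demarc_mod.corrected_distances(hfs_seqs)
    tree = demarc_mod.nj_tree(dm)
    tree_path = os.path.join(cfg.outdir, "hfs_nj.nwk")
    tree.write(tree_path)
    cons, fine = demarc_mod.demarcate_both(tree, hfs_seqs,
                                           derive_seed(seed, "demarc"),
                                           cfg.fit)
    part_path = os.path.join(cfg.outdir, "pe_partition.tsv")
    pd.DataFrame({
        "variant": list(fine.assignment),
        "fine_pe": [fine.assignment[v] for v in fine.assignment],
        "conservative_pe": [cons.assignment[v] for v in fine.assignment],
    }).to_csv(part_path, sep="\t", index=False)
    manifest.add("demarcate",
                 {"n_conservative": cons.n_pes(), "n_fine": fine.n_pes(),
                  "fit": dataclasses.asdict(cfg.fit)},
                 [tree_path, part_path])

    # --- abundance -------------------------------------------------------
    assignment = abundance_mod.build_assignment(table, hfs_set,
                                                fine.assignment)
    profile = abundance_mod.pe_abundance(table, assignment)
    ab_path = os.path.join(cfg.outdir, "pe_abundance.tsv")
    profile.frame.to_csv(ab_path, sep="\t", index=False)
    manifest.add("abundance", {"n_pes": fine.n_pes()}, [ab_path])

    # --- ecostats --------------------------------------------------------
    env = community.metadata_frame().set_index("sample_id")[
        ["temperature_C", "depth_um"]]
    hfs_counts = table.counts.loc[hfs_set.members]
    ord_res = ecostats.cca(hfs_counts, env)
    stats_rows = [("cca_total_inertia", ord_res.total_inertia),
                  ("cca_constrained_inertia", ord_res.constrained_inertia)]
    for name, frac in ord_res.predictor_fractions.items():
        stats_rows.append((f"cca_fraction_{name}", frac))
    for pe, leaves in fine.clades.items():
        members = [v for v in leaves if v in ord_res.variant_scores.index]
        res = ecostats.ordtest_cluster(
            ord_res.variant_scores, members, cfg.n_permutations,
            derive_seed(seed, "ordtest", pe), group_label=pe)
        if res.testable:
            stats_rows.append((f"ordtest_p_{pe}", res.p_value))
    pe_sample = profile.wide().fillna(0.0)
    pe_temp_counts = _pe_by_temperature_counts(table, assignment, community)
    if pe_temp_counts.shape[0] >= 2 and pe_temp_counts.shape[1] >= 2:
        g = ecostats.g_test(pe_temp_counts.to_numpy())
        stats_rows += [("g_statistic", g.g), ("g_p", g.p_value)]
    stats_path = os.path.join(cfg.outdir, "ecostats.tsv")
    pd.DataFrame(stats_rows, columns=["quantity", "value"]).to_csv(
        stats_path, sep="\t", index=False)
    manifest.add("ecostats", {"n_permutations": cfg.n_permutations},
                 [stats_path])

    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    manifest.write(manifest_path)
    return manifest


def _pe_by_temperature_counts(table, assignment, community) -> pd.DataFrame:
    temps = {s.sample_id: s.temperature for s in community.samples}
    counts: dict[str, dict[float, int]] = {}
    for v in table.counts.index:
        pe = assignment.pe_of(v)
        for sample in table.counts.columns:
            t = temps[sample]
            counts.setdefault(pe, {})[t] = (
                counts.get(pe, {}).get(t, 0) + int(table.counts.loc[v, sample]))
    return pd.DataFrame(counts).T.fillna(0).astype(int).sort_index()
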