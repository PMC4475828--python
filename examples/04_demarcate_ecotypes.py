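"""Fit the Stable Ecotype Model and demarcate putative ecotypes on a
neighbor-joining tree, in both conservative and fine-scale modes."""

import numpy as np

from ecodemarc import demarc, synth

rng = np.random.default_rng(7)
reference = "".join(rng.choice(list("ACGT"), size=324))
specs = [synth.EcotypeSpec(f"eco{i + 1}", niche_center=(60.0 + 3 * i,
                                                        100.0 + 150 * i),
                           niche_breadth=(2.0, 150.0), n_hfs=3)
         for i in range(3)]
haps = synth.generate_community_haplotypes(specs, reference, seed=7,
                                           separation_factor=10.0)
seqs = {f"{eco}_{i}": h for eco, hl in haps.items()
        for i, (h, _) in enumerate(hl)}

dm = demarc.corrected_distances(seqs)
curve = demarc.bin_curve(dm)
print("bin curve (complete-linkage clusters per identity criterion):")
for c, b in zip(curve.criteria, curve.bins):
    print(f"  identity >= {c:.4f}: {b} bins")
print("The plateau at 3 bins across the loose criteria is the signature")
print("of three deeply separated ecotypes; the extra bins at the strict")
print("end are within-ecotype variant diversity.")

fit = demarc.fit_ses(curve, len(seqs), seed=0, dm=dm)
print(f"\nML fit: npop={fit.ml.npop} (CI {fit.ci_npop}), "
      f"sigma={fit.ml.sigma}, omega={fit.ml.omega} per substitution")

tree = demarc.nj_tree(dm)
cons, fine = demarc.demarcate_both(tree, seqs, seed=0)
print(f"\nconservative demarcation: {cons.n_pes()} PEs")
print(f"fine-scale demarcation:   {fine.n_pes()} PEs")
for pe, leaves in fine.clades.items():
    print(f"  {pe}: {leaves}")
print("Every fine-scale PE nests inside a conservative PE by")
print("construction; here the three planted ecotypes are recovered")
print("exactly in both modes.")
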