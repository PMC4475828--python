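"""Perturbation-response tests: do PEs react differently to an
environmental shift (distinctness), and does each PE's internal
composition stay put while its total changes (interchangeability)?"""

import numpy as np
import pandas as pd

from ecodemarc import ecostats

# temperature-shift experiment: PE_A quadruples over 4 days, PE_B shrinks
rng = np.random.default_rng(13)
times = [0.0, 2.0, 4.0]
p_a = np.array([0.10, 0.20, 0.40])
n = 2000
counts = pd.DataFrame(
    [rng.binomial(n, p_a), rng.binomial(n, 1 - p_a)],
    index=["PE_A", "PE_B"], columns=times)

res = ecostats.perturbation_trend(counts)
print("PE x time interaction p =", f"{res.interaction_p:.2e}",
      f"(df={res.interaction_df})")
print(res.slopes.to_string())
print("The tiny interaction p says the two PEs changed their relative")
print("frequencies separately - they are ecologically distinct; the")
print("direction labels match the planted up/down responses.")

# homogeneity: the PE total shifts 5-fold but HFS shares stay constant
tot = np.array([200.0, 500.0, 1000.0])
hfs_counts = pd.DataFrame([0.5 * tot, 0.3 * tot], index=["hfs1", "hfs2"],
                          columns=times).astype(int)
lfs_counts = pd.Series(0.2 * tot, index=times).astype(int)
hom = ecostats.within_pe_homogeneity(hfs_counts, lfs_counts)
print("\nwithin-PE composition trends while the PE total shifts 5-fold:")
print(hom.components.to_string())
print(f"worst-case p = {hom.worst_p:.2f}")
print("Flat slopes (large p) mean every variant of the PE rose and fell")
print("in unison - the membership behaved as interchangeable individuals.")
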