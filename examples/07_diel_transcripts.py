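"""Diel transcript series: simulate two PEs with offset activity peaks,
normalize, and recover the expression-timing offset."""

import numpy as np

from ecodemarc import dieltx, synth

profiles = [synth.DielProfile("PE_surface", peak_hour=8.0, amplitude=1.0),
            synth.DielProfile("PE_subsurface", peak_hour=12.0,
                              amplitude=1.0)]
series = synth.simulate_diel_transcripts(
    profiles, timepoints=range(24), depth=4000, seed=17,
    missing=[5.0, 6.0, 21.0])       # failed sequencing reactions

norm = dieltx.normalize_diel(series)
print("normalized transcript series (geometric mean 1 per category):")
print(norm.values.round(2).to_string())

gm = np.exp(np.log(norm.values).mean(axis=1))
print("\nper-category geometric means:", np.round(gm.to_numpy(), 12))

t_surface = norm.values.loc["PE_surface"].idxmax()
t_sub = norm.values.loc["PE_subsurface"].idxmax()
print(f"\nrelative-abundance maxima: surface at {t_surface}h, "
      f"subsurface at {t_sub}h")
print("The surface population's share peaks before the subsurface one's,")
print("recovering the planted timing offset. Because these are relative")
print("shares, each maximum sits where the competitor is quietest - the")
print("ordering, not the absolute peak hour, is the identified quantity.")
print(f"missing timepoints excluded from the series: {series.missing}")
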