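"""Remove homopolymer frameshifts by excision against an in-frame
reference, and show the round-trip guarantee for insertion errors."""

import numpy as np

from ecodemarc import readclean as rc
from ecodemarc import synth

rng = np.random.default_rng(3)
reference = "".join(rng.choice(list("ACGT"), size=324))
ref = rc.ConsensusReference(reference)

model = synth.ErrorModel(p_ins=0.0015, p_del=0.0008,
                         run_length_exponent=1.0)
reads = []
for i in range(500):
    seq, n_ins, n_del = model.corrupt(reference, rng)
    reads.append((f"read{i}|ins{n_ins}|del{n_del}", seq))

passed, rejected, report = rc.clean_reads(reads, ref)
print(f"input {report.n_input}: passed {report.n_passed}, "
      f"gap-rejected {report.n_rejected_gap}, "
      f"quality-rejected {report.n_rejected_quality}")

roundtrip = sum(c.sequence == reference for c in passed)
print(f"{roundtrip}/{len(passed)} passed reads equal the source haplotype.")
print()
print("Insertion-only reads always clean back to their source (the extra")
print("homopolymer copies are excised); any deletion leaves a reference")
print("position uncovered and the read is dropped with reason 'gap'.")
print("Reads carrying BOTH an insertion and a deletion are length-neutral")
print("and a few can slip through as substitutions - the residual gap")
print("between the two counts above.")
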