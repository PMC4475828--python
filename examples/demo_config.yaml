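# Demo configuration: a small synthetic hot-spring community analysed
# end-to-end (synthesize -> clean -> count -> demarcate -> abundance ->
# ecostats). All randomness derives from `seed`.
outdir: demo_out
seed: 1
reference_length: 324

# community: three ecotypes on a temperature x depth grid
n_ecotypes: 3
n_hfs: 2
n_lfs: 1
hfs_distance: 2
separation_factor: 4.0
temperatures: [60.0, 63.0, 66.0]
depths: [100.0, 300.0, 500.0]
depth_per_sample: 250

# homopolymer error rates per run, scaling linearly with run length
p_ins: 0.0015
p_del: 0.0008
run_length_exponent: 1.0

hfs_threshold: 50
n_permutations: 999

fit:
  n_replicates: 30
  npop_max: 5
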