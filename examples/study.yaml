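# One mediator-set size of the full evaluation study.
# For the complete design use p_levels: [200, 400, 600] and n_reps: 1000
# (hours of CPU); the settings below finish on a laptop.
p_levels: [200]
n_reps: 25
methods: [MITM, HIMA, HDMA]
alpha: 0.05
base_seed: 1
out_dir: results
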