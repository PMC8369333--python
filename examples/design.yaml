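# Reduced Monte-Carlo design: error rates of the interval Bayes factor and
# the three ROPE tests around the n=170 planning scenario.
settings: ["null", "small"]
n_grid: [160, 170, 180]
prior_scales: [1.0]
regions: [[-0.05, 0.05], [-0.1, 0.1], [-0.15, 0.15]]
methods: [noh_bf, rope_hpd95, rope_full, rope_support]
reps: 300
master_seed: 1
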