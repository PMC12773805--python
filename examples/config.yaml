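# Example simulation configuration (every field can be overridden by a
# CLI flag of the same name).
beta: 0.01            # bottleneck fraction: 0.01 stringent, 0.15 relaxed
gamma: 0.98           # cost-of-cooperation discount for C-C sporulation
epsilon: 0.5          # privatization of germination public goods
epsilon_first_cycle: 0.8
n_sharing: 50         # public-good sharing divisor n
n_max: 10000          # carrying capacity (scaled; the full model uses 1e6)
n_cycles: 10
readout_cycles: [10]
coop_threshold: 0.5
mutation_halfwidth: 0.1
tradeoff_slope: -1.15
mutation_prob: 1.0
init_mean: 0.5
init_sd: 0.15
germination_mode: communal
seed: 42
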