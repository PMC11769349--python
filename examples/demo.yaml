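# Self-contained demonstration: synthetic construct + simulated library.
# Coordinates are 0-based half-open throughout.
sample_id: demo
references:
  demo_seed: 0          # packaged synthetic plasmid + host fixture
simulate:
  n_pairs: 5000
  read_len: 150
  frag_len_mean: 300
  frag_len_sd: 60
  error_rate: 0.002
  seed: 1
  class_fractions:
    replicon_sense: 0.950
    antisense: 0.001
    backbone: 0.020
    host: 0.010
    artifact: 0.019
  polya_len_dist: {41: 0.142857, 42: 0.142857, 43: 0.142857, 44: 0.142858,
                   45: 0.142857, 46: 0.142857, 47: 0.142857}
# Orthogonal mass measurements (optional): uncomment to evaluate the
# regulatory DNA limits against real qPCR/fluorometry numbers.
# measured_ng_per_mg: 120.0
# measured_ng_per_dose: 2.5
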