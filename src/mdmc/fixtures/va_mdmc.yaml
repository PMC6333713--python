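# Reference fit: base model, visual-auditory task (aggregated data).
task: visual-auditory
variant: mdmc
mu_c: 0.62
boundary: 57.7
start_shape: 2.7
mu_r: 311.0
sigma_r: 40.5
sigma: 4.0
dt: 1.0
automatic:
  visual:
    amplitude_magnitude: 15.1
    tau: 51.4
    shape: 2.0
  auditory:
    amplitude_magnitude: 6.5
    tau: 35.5
    shape: 2.0
reference:
  g2: 136.2
  bic: 186.6
  n_free: 9
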