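# Reference fit: faster-neutral variant, visual-auditory task (aggregated data).
task: visual-auditory
variant: fn-mdmc
mu_c: 0.58
boundary: 55.6
start_shape: 3.5
mu_r: 315.0
mu_rn: 302.0
sigma_r: 35.3
sigma: 4.0
dt: 1.0
automatic:
  visual:
    amplitude_magnitude: 16.7
    tau: 46.6
    shape: 2.0
  auditory:
    amplitude_magnitude: 5.3
    tau: 32.0
    shape: 2.0
reference:
  g2: 98.6
  bic: 154.6
  n_free: 10
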