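# Reference fit: faster-neutral variant, visual-tactile task (aggregated data).
task: visual-tactile
variant: fn-mdmc
mu_c: 0.66
boundary: 64.1
start_shape: 2.9
mu_r: 317.0
mu_rn: 303.0
sigma_r: 36.8
sigma: 4.0
dt: 1.0
automatic:
  visual:
    amplitude_magnitude: 19.8
    tau: 38.5
    shape: 2.0
  tactile:
    amplitude_magnitude: 7.1
    tau: 28.2
    shape: 2.0
reference:
  g2: 114.5
  bic: 170.5
  n_free: 10
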