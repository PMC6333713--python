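# Reference fit: base model, visual-tactile task (aggregated data).
task: visual-tactile
variant: mdmc
mu_c: 0.52
boundary: 54.6
start_shape: 3.1
mu_r: 313.0
sigma_r: 33.4
sigma: 4.0
dt: 1.0
automatic:
  visual:
    amplitude_magnitude: 13.4
    tau: 39.0
    shape: 2.0
  tactile:
    amplitude_magnitude: 6.1
    tau: 28.5
    shape: 2.0
reference:
  g2: 126.1
  bic: 176.5
  n_free: 9
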