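# Default configuration for WSS-driven vessel-wall remodeling runs.
#
# The probability coefficients (probabilities:) and the conversion scale
# were frozen by calibrate_defaults against the reference endpoints
# (stabilized VSMC count 1282, ECM count 1313); the WSS source is the
# reference low-WSS sector profile. See docs/methods.md.
geometry:
  grid_size: 100
  center: [50.0, 50.0]
  lumen_radius: 20.0
  outer_radius: 26.0
  unit_length: 76.75        # um per lattice unit
clocks:
  dt: 1                     # hours per tick
  vsmc_cycle: 12            # h
  ecm_cycle: 4              # h
  total_ticks: 800
damage:
  wss0: 1.0                 # Pa, low-WSS damage threshold
  recovery_rate: 0.0075     # per-hour decay exponent lambda
  attenuation: 0.9          # per-layer coefficient kappa
biochem:
  et: {M: 8.0e-4, delta: 0.6, alpha: 0.4, k: 3.63, n: 1.68}
  "no": {a: 4.365e-7, b: -9.399e-7, c: 6.348e-7, d: -9.939e-8, e: 9.333e-9}
  mmp9: {beta: 4.939e-8, gamma: 2.218e-7}
  conversion:
    scale: 0.005
    half_content: 8.0e+4    # pg
    printed_constants: [16.67, 1.45e-9, 8.0e+4]
  n_ec_per_site: 1.0
probabilities:              # frozen by calibration (see docs/methods.md)
  alpha_div: 0.5705
  alpha_apop: 0.0713
  alpha_gen: 0.1949
  alpha_deg: 0.0244
burden_threshold: 0.40
vsmc_fraction: 0.5
wss_source:
  type: sector              # reference low-WSS sector profile
  tau_base: 1.2             # Pa
  tau_min: 0.5              # Pa
  center_deg: 90.0
  width_deg: 300.0
  n_samples: 360
seed: 1
snapshot_every: 100
output_dir: null
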