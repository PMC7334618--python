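# Default narloop run configuration: reproduces the study's nominal setup.
#
# Sections:
#   params       - overrides of the shipped nominal CircuitParams (empty = nominal)
#   calibration  - production anchors pinning the free constants
#   dose_response- characterization grids and the +/-15% uncertainty ensemble
#   perturbation - malonyl-CoA step scenarios (fractions, onset, horizon)
#   robustness   - parameter-grid scan settings per controller variant

params: {}

calibration:
  target_titer: 1.0          # g/L at 36 h, all variants unperturbed
  target_kaempferol: 5.0e-6  # g/L kaempferol while sensing 1 g/L naringenin
  target_drop: 0.25          # open-loop naringenin loss at the anchor perturbation
  anchor_p: 0.4              # malonyl-CoA decrease used for the Km_M anchor

dose_response:
  naringenin_grid: {start: 0.05, stop: 2.0, num: 40}   # g/L
  antisigma_grid: {start: 0.01, stop: 200.0, num: 40, log: true}  # molecules/cell
  chs_grid: {start: 1.0e4, stop: 1.0e7, num: 60, log: true}       # molecules/cell
  m_frac_list: [1.0, 0.8, 0.6, 0.4]
  rel_uncertainty: 0.15
  n_samples: 200
  seed: 0

perturbation:
  p_list: [0.2, 0.4, 0.6]
  t_on: 1.0                  # h
  horizon: 36.0              # h
  settling_band: 0.05
  rel_uncertainty: 0.15
  n_samples: 50
  seed: 0

robustness:
  subsample: 2500            # antithetic grid target size (of 3888 raw combinations)
  seed: 0
  best_case:
    p: 0.6
    subsample: 400
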