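# Small demonstration pipeline: two simulated sites, a dozen specimens.
seed: 7
out_dir: zoomsid_demo_out
preprocess:
  snr: 3.5
  baseline_window: 100.0
  smooth_points: 5
  deisotope_tol: 0.15
  merge_tol: 0.3
  min_presence: 2
classify:
  tol: 0.5
  min_common: 4
  pair_mode: both
simulate:
  dropout_prob: 0.05
  noise_sd: 0.02
  n_contaminants: 8
  sites:
    - site_id: DEMO-A
      n_specimens: 8
      preservation: 1.0
      taxon_mix: {"Capra hircus": 0.6, "Ovis aries": 0.2, "Neotragus moschatus": 0.2}
      dates:
        - {context: T11, start: 655, end: 710, basis: radiocarbon}
        - {context: T14, start: 670, end: 770, basis: radiocarbon}
    - site_id: DEMO-B
      n_specimens: 6
      preservation: 0.5
      taxon_mix: {"Capra hircus": 0.7, "Cephalophus spp.": 0.3}
      dates:
        - {context: L1, start: 701, end: 900, basis: ceramic}
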