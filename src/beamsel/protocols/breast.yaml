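name: breast
prescription_gy: 35.0
fractions: 5
protocol: RTOG 0413
constraints:
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 35.0, volume: 0.95}
  - {structure: ipsilateral_breast, kind: max_dose_at_volume, dose_gy: 17.5, volume: 0.4}
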