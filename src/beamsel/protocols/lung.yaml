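name: lung
prescription_gy: 50.0
fractions: 5
protocol: RTOG 0813
constraints:
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 50.0, volume: 0.95}
  - {structure: proximal_bronchus, kind: max_dose_at_absolute_volume, dose_gy: 18.0, volume: 4.0}
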