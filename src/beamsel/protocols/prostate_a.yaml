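name: prostate_a
prescription_gy: 36.25
fractions: 5
protocol: RTOG 0938
constraints:
  - {structure: rectum, kind: max_dose_at_volume, dose_gy: 18.12, volume: 0.5}
  - {structure: bladder, kind: max_dose_at_volume, dose_gy: 18.12, volume: 0.5}
  - {structure: femoral_heads, kind: max_dose_at_absolute_volume, dose_gy: 20.0, volume: 10.0}
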