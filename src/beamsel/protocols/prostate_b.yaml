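name: prostate_b
prescription_gy: 38.0
fractions: 4
protocol: Fuller et al.
constraints:
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 38.0, volume: 0.95}
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 47.5, volume: 0.5}
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 57.0, volume: 0.15}
  - {structure: urethra, kind: max_dose_at_volume, dose_gy: 39.9, volume: 0.5}
  - {structure: rectum, kind: max_dose_at_absolute_volume, dose_gy: 28.5, volume: 2.0}
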