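name: liver
prescription_gy: 42.75
fractions: 3
protocol: Vautravers-Dewas et al.
constraints:
  - {structure: ptv, kind: min_dose_at_volume, dose_gy: 42.75, volume: 0.95}
  - {structure: normal_liver, kind: max_dose_at_volume, dose_gy: 15.0, volume: 0.5}
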