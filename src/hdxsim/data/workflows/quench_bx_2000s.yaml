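# hdxsim workflow config
esi_retention: 1.0
stages:
- label: labeling
  duration_s: 600.0
  acidity: 7.4
  scale: pD
  temp_K: 295.15
  direction: H_to_D
  protected: true
  target_occupancy: 1.0
- label: back-exchange
  duration_s: 2000.0
  acidity: 2.5
  scale: pH_in_H2O
  temp_K: 273.15
  direction: D_to_H
  protected: false
  target_occupancy: 0.0
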