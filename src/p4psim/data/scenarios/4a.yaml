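id: 4a
label: Equal allocation
group: 4. P4P with motivation, gaming and bonus delay, with different bonus distribution
  strategies
overrides:
  enabled: true
  motivation_gain: 2.5
  gaming_feedback: 0.45
  tau_disbursement: 18.0
  mu_quality: 1.0
  mu_volume: 0.0
  gaming_max: 0.16
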