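id: 3d
label: Bonus delay
group: 3. P4P with one additional feature
overrides:
  enabled: true
  tau_disbursement: 18.0
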