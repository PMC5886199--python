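id: 3a
label: Motivation
group: 3. P4P with one additional feature
overrides:
  enabled: true
  motivation_gain: 1.3
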