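id: 3c
label: High-level gaming
group: 3. P4P with one additional feature
overrides:
  enabled: true
  gaming_init: 0.95
  gaming_feedback: 0.6
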