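id: 3b
label: Low-level gaming
group: 3. P4P with one additional feature
overrides:
  enabled: true
  gaming_init: 0.1
  gaming_max: 0.1
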