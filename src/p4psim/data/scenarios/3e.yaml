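id: 3e
label: Low bonuses
group: 3. P4P with one additional feature
overrides:
  enabled: true
  bonus_rate: 0.002
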