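id: '2'
label: P4P only
group: 2. P4P
overrides:
  enabled: true
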