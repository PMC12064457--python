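# exaggerated class effects (stress preset for quick demonstrations)
band_overrides:
  - centre: 1773.0
    width: 6.0
    class_shift: 6.0
  - centre: 1773.0
    width: 20.0
    class_delta: 0.015
  - centre: 2093.0
    width: 6.0
    class_shift: 6.0
  - centre: 2093.0
    width: 20.0
    class_delta: 0.014
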