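# negative control: identical cohort structure, all class effects zeroed
null_effects: true
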