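# the study-structure cohort: 206 control / 103 cancer, 3 replicates,
# calibrated class effects at 1773 and 2093 cm^-1
{}
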