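AR_LBD_synthetic	1700	73	70	71
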