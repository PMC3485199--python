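partner	expression_class
VPS21	periodic
YPT6	periodic
YPT31	periodic
SEC4	aperiodic
YPT1	aperiodic
YPT7	aperiodic
YPT10	aperiodic
YPT32	aperiodic
YPT52	aperiodic
YPT53	aperiodic
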