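variable,very_low,low,medium,high,very_high
DB,7.199,31.0088,63.8118,109.3561,169.6175
non-DB,49.1659,109.6643,156.3428,188.1021,212.7317
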