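level,frequency
1,219
2,221
3,217
4,221
5,219
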