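method,row,very_low,low,medium,high,very_high
reference,C,2.92,7.18,15.41,30.66,43.83
chisq,inner,2.92,7.18,14.48,23.44,43.83
chisq,outer,5.11,9.52,15.41,30.66,47.44
chisq,sigma,69.36,,,,
ridit,inner,2.92,7.18,15.41,26.65,42.35
ridit,outer,3.98,9.97,17.05,30.66,43.83
ridit,sigma,69.18,,,,
ahp,inner,2.92,7.18,15.41,24.12,40.16
ahp,outer,6.74,11.95,17.02,30.66,43.83
ahp,sigma,66.71,,,,
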