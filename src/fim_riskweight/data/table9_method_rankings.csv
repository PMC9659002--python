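variable,rfm_rank,ahp_weight,ahp_rank,chisq_weight,chisq_rank,ridit_weight,ridit_rank
Smoking,1,0.015,3,0.042,3,0.002,24
LPA,2,0.022,10,0.037,9,0.013,18
CW,3,0.010,22,0.047,1,0.032,8
LBW,4,0.007,24,0.042,4,0.023,13
IDY,5,0.129,18,0.020,22,0.067,3
DLN,6,0.016,16,0.034,13,0.021,16
VAD,7,0.015,19,0.043,2,0.008,20
LBD,8,0.037,6,0.034,15,0.003,23
AP,9,0.142,2,0.027,20,0.040,6
DHS,10,0.038,5,0.034,14,0.024,12
HAP,11,0.017,15,0.036,11,0.025,11
DLF,12,0.021,12,0.035,12,0.021,15
DB,13,0.016,17,0.003,24,0.245,1
DLV,14,0.021,11,0.037,10,0.014,17
AU,15,0.014,20,0.033,17,0.033,7
DU,16,0.011,21,0.038,6,0.006,22
HBM,17,0.020,13,0.024,21,0.054,4
CS,18,0.009,23,0.039,5,0.007,21
UWS,19,0.025,9,0.038,7,0.023,14
HFP,20,0.020,14,0.018,23,0.070,2
DLG,21,0.026,8,0.031,19,0.031,9
OAP,22,0.167,1,0.033,16,0.025,10
USX,23,0.026,7,0.032,18,0.048,5
SHS,24,0.083,4,0.038,8,0.010,19
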