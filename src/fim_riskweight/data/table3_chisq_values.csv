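variable,chisq,weight
DB,41.37,0.0030
TB,516.68,0.0372
UWS,523.82,0.0377
USN,533.08,0.0384
NHF,532.60,0.0383
HAP,497.60,0.0358
NEB,553.70,0.0399
DBF,581.37,0.0418
CW,646.50,0.0465
CS,545.02,0.0392
LBW,581.04,0.0418
SHS,522.60,0.0376
AU,451.03,0.0325
DU,531.80,0.0383
DLF,491.40,0.0354
DLV,506.60,0.0365
USX,449.78,0.0324
LPA,514.90,0.0371
HFP,246.80,0.0178
HBM,331.50,0.0239
HBP,160.50,0.0116
IDY,281.30,0.0202
Smoking,586.03,0.0422
VAD,595.18,0.0428
LBD,470.50,0.0339
AP,370.06,0.0266
OAP,453.13,0.0326
DHS,473.13,0.0341
DLG,429.40,0.0309
DLN,475.24,0.0342
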