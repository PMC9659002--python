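variable,DB,TB,UWS,USN,NHF,HAP,NEB,DBF,CW,CS,LBW,SHS,AU,DU,DLF,DLV,USX,LPA,HFP,HBM,HBP,Smoking,IDY,VAD,LBD,AP,OAP,DHS,DLG,DLN
DB,1.00,0.20,0.14,0.09,0.50,0.13,0.25,0.33,0.50,1.00,3.33,0.11,1.00,3.33,0.33,0.17,0.17,3.33,3.33,3.33,3.33,0.14,3.33,3.33,0.25,0.20,0.14,0.33,1.00,0.33
TB,5.00,1.00,0.11,0.10,0.50,0.25,1.00,1.00,2.00,2.00,3.33,0.13,1.00,1.00,2.00,2.00,2.00,2.00,2.00,2.00,2.00,0.20,2.00,2.00,0.25,0.20,0.14,0.33,0.33,0.33
UWS,7.00,9.00,1.00,8.00,8.00,8.00,1.00,1.00,1.00,1.00,1.00,0.17,0.50,0.50,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.11,1.00,1.00,0.25,0.14,0.10,0.33,1.00,0.33
USN,11.00,10.00,1.00,1.00,2.00,0.50,1.43,1.43,1.43,1.43,1.43,0.20,0.33,0.33,0.50,0.50,0.50,0.50,0.50,0.50,0.50,0.13,0.33,0.33,0.25,0.13,0.10,0.33,0.14,0.33
NHF,2.00,2.00,1.50,0.50,1.00,0.50,1.00,1.00,1.00,1.00,1.00,0.11,0.50,1.00,0.20,0.20,0.20,0.20,1.00,1.00,1.00,0.11,0.33,1.00,0.25,0.14,0.10,0.33,2.00,2.00
HAP,8.00,4.00,3.00,2.00,2.00,1.00,0.33,0.33,0.50,1.00,2.00,0.14,1.00,2.00,0.50,1.00,0.33,0.50,1.00,0.33,0.20,0.11,2.00,2.00,0.25,0.20,0.11,0.33,0.33,2.00
NEB,4.00,1.00,1.00,0.70,1.00,3.00,1.00,1.00,1.00,1.00,1.00,0.20,0.50,1.00,0.50,0.50,1.00,1.00,1.00,1.00,1.00,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.33,2.00
DBF,3.00,1.00,1.00,0.70,1.00,3.00,1.00,1.00,1.00,1.00,1.00,0.14,0.50,1.00,0.50,0.50,2.00,2.00,2.00,2.00,1.00,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.50,1.43
CW,2.00,0.50,1.00,0.70,1.00,2.00,1.00,1.00,1.00,1.00,1.00,0.14,0.50,1.00,0.50,0.50,0.11,0.20,0.20,0.33,1.00,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.50,1.43
CS,1.00,0.50,1.00,0.70,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.14,0.50,1.00,0.50,0.50,0.14,0.14,0.14,0.14,0.14,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.50,1.43
LBW,0.30,0.30,1.00,0.70,1.00,0.50,1.00,1.00,1.00,1.00,1.00,0.11,0.25,0.33,0.25,0.25,0.11,0.11,0.11,0.11,0.11,0.09,0.33,0.33,0.25,0.11,0.09,0.33,0.33,0.33
SHS,9.00,8.00,6.00,5.00,9.00,7.00,5.00,7.00,7.00,7.00,9.00,1.00,2.00,10.00,3.33,3.33,10.00,10.00,10.00,10.00,10.00,0.50,10.00,10.00,0.25,1.00,0.50,0.33,0.33,10.00
AU,1.00,1.00,2.00,3.00,2.00,1.00,2.00,2.00,2.00,2.00,4.00,0.50,1.00,1.00,0.50,0.50,0.14,0.14,0.14,0.14,0.14,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.50,1.43
DU,0.30,1.00,2.00,3.00,1.00,0.50,1.00,1.00,1.00,1.00,3.00,0.10,1.00,1.00,0.50,0.50,0.14,0.14,0.14,0.14,0.14,0.11,1.00,1.00,0.25,0.14,0.11,0.33,0.50,1.43
DLF,3.00,0.50,1.00,2.00,5.00,2.00,2.00,2.00,2.00,2.00,4.00,0.30,2.00,2.00,1.00,1.00,2.00,2.00,2.00,2.00,2.00,0.11,1.00,1.00,1.00,0.11,0.09,0.33,1.00,1.00
DLV,6.00,0.50,1.00,2.00,5.00,1.00,2.00,2.00,2.00,2.00,4.00,0.30,2.00,2.00,1.00,1.00,1.00,2.00,2.00,2.00,2.00,0.11,1.00,1.00,1.00,0.11,0.09,0.33,1.00,1.00
USX,6.00,0.50,1.00,2.00,5.00,3.00,1.00,0.50,9.00,7.00,9.00,0.10,7.00,7.00,0.50,1.00,1.00,1.00,1.00,1.00,1.00,0.09,0.50,0.50,0.50,0.09,0.08,0.33,1.00,1.00
LPA,0.30,0.50,1.00,2.00,5.00,2.00,1.00,0.50,5.00,7.00,9.00,0.10,7.00,7.00,0.50,0.50,1.00,1.00,1.00,1.00,1.00,0.09,0.50,0.50,0.50,0.09,0.08,0.33,1.00,1.00
HFP,0.30,0.50,1.00,2.00,1.00,1.00,1.00,0.50,5.00,7.00,9.00,0.10,7.00,7.00,0.50,0.50,1.00,1.00,1.00,1.00,1.00,0.09,0.50,0.50,0.50,0.09,0.08,0.33,1.00,1.00
HBM,0.30,0.50,1.00,2.00,1.00,3.00,1.00,0.50,3.00,7.00,9.00,0.10,7.00,7.00,0.50,0.50,1.00,1.00,1.00,1.00,1.00,0.09,0.50,0.50,0.50,0.09,0.08,0.33,1.00,1.00
HBP,0.30,0.50,1.00,2.00,1.00,5.00,1.00,1.00,1.00,7.00,9.00,0.10,7.00,7.00,0.50,0.50,1.00,1.00,1.00,1.00,1.00,0.09,0.50,0.50,0.50,0.09,0.08,0.33,1.00,1.00
Smoking,7.00,5.00,9.00,8.00,9.00,9.00,9.00,9.00,9.00,9.00,11.00,2.00,9.00,9.00,9.00,9.00,11.00,11.00,11.00,11.00,11.00,1.00,20.00,20.00,20.00,1.30,1.00,2.50,2.00,2.00
IDY,0.30,0.50,1.00,3.00,3.00,0.50,1.00,1.00,1.00,1.00,3.00,0.10,1.00,1.00,1.00,1.00,2.00,2.00,2.00,2.00,2.00,0.05,1.00,0.50,0.50,0.09,0.08,0.33,1.00,1.00
VAD,0.30,0.50,1.00,3.00,1.00,0.50,1.00,1.00,1.00,1.00,3.00,0.10,1.00,1.00,1.00,1.00,2.00,2.00,2.00,2.00,2.00,0.05,2.00,1.00,0.50,0.09,0.08,0.33,1.00,1.00
LBD,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,4.00,1.00,1.00,2.00,2.00,2.00,2.00,2.00,0.05,2.00,2.00,1.00,0.09,0.08,0.33,1.00,1.00
AP,5.00,5.00,7.00,8.00,7.00,5.00,7.00,7.00,7.00,7.00,9.00,1.00,7.00,7.00,9.00,9.00,11.00,11.00,11.00,11.00,11.00,0.77,11.00,11.00,11.00,1.00,1.00,20.00,100.00,100.00
OAP,7.00,7.00,10.00,10.00,10.00,9.00,9.00,9.00,9.00,9.00,11.00,2.00,9.00,9.00,11.00,11.00,13.00,13.00,13.00,13.00,13.00,1.00,13.00,13.00,13.00,1.00,1.00,20.00,100.00,100.00
DHS,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,3.00,0.40,3.00,3.00,3.00,0.05,0.05,1.00,1.11,1.11
DLG,1.00,3.00,1.00,7.00,0.50,3.00,3.00,2.00,2.00,2.00,3.00,3.00,2.00,2.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.50,1.00,1.00,1.00,0.01,0.01,0.90,1.00,1.00
DLN,3.00,3.00,3.00,3.00,0.50,0.50,0.50,0.70,0.70,0.70,3.00,0.10,0.70,0.70,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.50,1.00,1.00,1.00,0.01,0.01,0.90,1.00,1.00
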