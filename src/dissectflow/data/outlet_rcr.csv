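name,Rp,C,Rd
RCCA,0.80,6.10,4.53
RSCA,0.13,7.64,1.89
LCCA,0.78,6.14,4.40
LSCA,0.12,7.87,1.72
Hepatic,0.24,1.15,4.06
Splenic,0.14,2.04,2.30
M Coeliac,0.23,1.18,3.95
SMA,0.13,3.87,1.15
R Renal 1,0.48,2.37,1.94
R Renal 2,1.11,1.19,4.45
L Renal,0.32,3.34,1.30
IMA,0.68,0.73,6.13
M Sacral 1,0.54,0.52,9.04
M Sacral 2,0.78,0.36,13.12
L Int Iliac,0.10,0.15,3.87
R Int Iliac,0.13,0.15,5.15
L Ext Iliac,0.06,0.49,2.49
R Ext Iliac,0.06,0.55,2.18
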