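regionA,regionB,p,distance,category
IPL.L,dACC/msFC,0.002,85.386,FPN-CON
IPL.L,sup frontal.L,0.002,104.643,FPN-DMN
IPS.L,dACC/msFC,0.003,80.696,FPN-CON
aPFC.R,aI/fO.L,0.003,79.736,CON-CON
vmPFC,latP.L,0.004,130.281,DMN-DMN
sup frontal.R,inf templ.L,0.008,134.846,DMN-DMN
amPFC,lat cereb.R,0.010,138.559,DMN-CN
aPFC.R,dACC/msFC,0.011,58.500,CON-CON
Precun.L,inf templ.R,0.012,115.336,FPN-DMN
vmPFC,retro splen,0.013,97.096,DMN-DMN
Precun.L,dACC/msFC,0.015,88.591,FPN-CON
IPL.R,IPS.R,0.015,27.383,FPN-FPN
aPFC.L,sup frontal.R,0.019,65.390,CON-DMN
IPS.R,dACC/msFC,0.019,83.252,FPN-CON
IPS.R,Precun.R,0.020,23.245,FPN-FPN
sup frontal.R,pCC,0.020,82.324,DMN-DMN
Precun.L,sup frontal.R,0.020,120.936,FPN-DMN
aPFC.L,dACC/msFC,0.021,62.998,CON-CON
Precun.R,sup frontal.R,0.022,114.397,FPN-DMN
latP.L,lat cereb.R,0.022,111.618,DMN-CN
sup frontal.L,latP.R,0.023,134.610,DMN-DMN
mCC,lat cereb.L,0.026,83.918,FPN-CN
aPFC.L,inf cereb.L,0.027,147.951,CON-CN
IPL.L,aPFC.L,0.037,114.410,FPN-CO
dlPFC.R,Precun.R,0.038,103.820,FPN-FPN
IPL.L,lat cereb.R,0.044,115.178,FPN-CN
aI/fO.L,pCC,0.044,73.509,CO-DMN
IPL.L,aPFC.R,0.044,137.908,FPN-CON
parahippo.R,retro splen,0.047,43.527,DMN-DMN
sup frontal.L,lat cereb.L,0.048,144.127,DMN-CN
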