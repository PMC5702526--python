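name,abbreviation,x,y,z,network
Dorsolateral prefrontal cortex,dlPFC,-45,28,31,FPN
Dorsolateral prefrontal cortex,dlPFC,48,28,30,FPN
Frontal,frontal,-43,8,36,FPN
Frontal,frontal,46,8,34,FPN
Mid-cingulate cortex,mCC,2,-26,32,FPN
Inferior parietal lobule,IPL,-53,-49,42,FPN
Inferior parietal lobule,IPL,57,-44,46,FPN
Intraparietal sulcus,IPS,-32,-57,49,FPN
Intraparietal sulcus,IPS,34,-59,44,FPN
Precuneus,Precun,-8,-71,44,FPN
Precuneus,Precun,13,-68,46,FPN
Anterior medial prefrontal cortex,amPFC,2,61,13,DMN
Ventromedial prefrontal cortex,vmPFC,-2,43,-11,DMN
Superior frontal cortex,sup frontal,-15,47,49,DMN
Superior frontal cortex,sup frontal,20,46,49,DMN
Inferior temporal,inf templ,-65,-35,-17,DMN
Inferior temporal,inf templ,71,-18,-21,DMN
Parahippocampal,parahippo,-23,-28,-19,DMN
Parahippocampal,parahippo,28,-28,-18,DMN
Posterior cingulate cortex,pCC,0,-33,40,DMN
Lateral parietal,latP,-49,-66,43,DMN
Lateral parietal,latP,59,-66,41,DMN
Retrosplenial,retro splen,5,-52,9,DMN
Lateral cerebellum,lat cereb,-34,-72,-29,CN
Lateral cerebellum,lat cereb,34,-66,-31,CN
Inferior cerebellum,inf cereb,-20,-85,-33,CN
Inferior cerebellum,inf cereb,20,-87,-33,CN
Anterior prefrontal cortex,aPFC,-29,57,7,CON
Anterior prefrontal cortex,aPFC,30,57,15,CON
Anterior insula/frontal operculum,aI/fO,-37,17,0,CON
Anterior insula/frontal operculum,aI/fO,40,19,-3,CON
Anterior thalamus,ant thal,-12,-14,5,CON
Anterior thalamus,ant thal,12,-14,6,CON
Dorsal anterior cingulate/medial superior frontal cortex,dACC/msFC,1,17,45,CON
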