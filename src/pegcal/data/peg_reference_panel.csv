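label,source,mw_da,mw_sd,rh_nm,rh_sd
APEG 400,APEG,378,30,0.568,0.027
APEG 600,APEG,521,51,0.672,0.054
APEG 1000,APEG,997,77,0.944,0.025
APEG 2000,APEG,1887,20,1.602,0.284
APEG 4000,APEG,3981,82,1.784,0.165
APEG 6000,APEG,6185,165,2.343,0.111
APEG 8000,APEG,8232,162,2.749,0.101
APEG 10000,APEG,10535,907,3.306,0.063
APEG 12000,APEG,13646,1359,3.522,0.061
APEG 20000,APEG,19118,631,4.415,0.015
SPEG 1450,SPEG,1348,64,1.203,0.097
SPEG 4600,SPEG,4384,436,2.095,0.045
SPEG 8000,SPEG,8350,301,2.572,0.299
SPEG 10000,SPEG,10641,219,3.474,0.214
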