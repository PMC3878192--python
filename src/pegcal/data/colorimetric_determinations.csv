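sample,particle_nm,h_rms_nm,h_rms_sd,mw_da,mw_sd
SPEG 1450,16,3.398,0.298,1561,259
SPEG 4600,16,6.017,0.368,4621,537
SPEG 8000,16,8.086,0.279,8096,532
SPEG 10000,16,9.903,0.432,11919,989
SPEG 1450,26,3.444,0.411,1611,362
SPEG 4600,26,6.096,0.349,4736,515
SPEG 8000,26,7.974,0.397,7893,747
SPEG 10000,26,10.032,0.387,12212,897
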