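label,rg_nm,rg_sd,h_rms_nm,h_rms_sd
APEG 400,0.668,0.032,1.636,0.078
APEG 600,0.791,0.064,1.938,0.156
APEG 1000,1.111,0.029,2.721,0.072
APEG 2000,1.885,0.334,4.617,0.818
APEG 4000,2.099,0.194,5.141,0.475
APEG 6000,2.756,0.131,6.751,0.320
APEG 8000,3.234,0.119,7.922,0.291
APEG 10000,3.889,0.074,9.526,0.182
APEG 12000,4.144,0.072,10.151,0.176
APEG 20000,5.194,0.018,12.723,0.043
SPEG 1450,1.415,0.114,3.466,0.280
SPEG 4600,2.465,0.053,6.038,0.130
SPEG 8000,3.026,0.352,7.412,0.862
SPEG 10000,4.087,0.252,10.011,0.617
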