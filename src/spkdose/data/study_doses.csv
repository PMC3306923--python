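subject_id,community,season,body_wt_kg,pbpk,spk1,spk2,spk3
R1,agricultural,summer,15.5,0.004,0.546,0.273,1.140
R2,agricultural,summer,21.4,0.003,0.281,0.246,0.380
R3,agricultural,summer,14.5,0.004,0.043,0.022,0.014
R4,agricultural,summer,16.8,0.003,0.831,1.439,0.987
R5,agricultural,summer,13.4,0.004,0.338,0.213,0.158
R6,agricultural,summer,19.6,0.003,n.a.,0.840,0.520
S1,urban,summer,17.3,0.003,0,0,0
S2,urban,summer,18.2,0,0.224,0.112,0.488
S3,urban,summer,15,0,n.a.,3.357,2.497
S4,urban,summer,15.5,0,1.881,1.450,1.282
S5,urban,summer,16.8,0.004,n.a.,n.a.,0.326
S6,urban,summer,22.7,0.440,0.808,0.820,0.672
S7,urban,summer,14.5,0,n.a.,n.a.,1.056
R1,agricultural,fall,15.5,0.004,1.881,2.274,1.973
R2,agricultural,fall,21.4,0.003,0.051,0.204,0.229
R3,agricultural,fall,14.5,0.012,0.347,0.980,0.944
R4,agricultural,fall,16.8,0.003,0.366,0.541,0.603
R5,agricultural,fall,13.4,0.018,0.082,0.483,0.368
R6,agricultural,fall,19.6,0.005,0.476,0.476,0.250
S1,urban,fall,17.3,2.302,9.125,5.496,3.647
S2,urban,fall,18.2,0.003,0.172,0.949,1.110
S3,urban,fall,15,0.004,1.060,1.060,1.219
S4,urban,fall,15.5,0,0.956,1.260,1.017
S5,urban,fall,16.8,0,1.028,1.184,0.922
S6,urban,fall,22.7,0.001,0.041,0.969,0.934
S7,urban,fall,14.5,0.006,n.a.,n.a.,1.513
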