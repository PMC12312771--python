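scenario,level,matrix,row,ATT,SN,PBC,INT,BEH
S1_low_unequal,within,B,ATT,0,0,0,0,0
S1_low_unequal,within,B,SN,0,0,0,0,0
S1_low_unequal,within,B,PBC,0,0,0,0,0
S1_low_unequal,within,B,INT,0.43,0.16,0.31,0,0
S1_low_unequal,within,B,BEH,0,0,0.53,0.07,0
S1_low_unequal,within,Psi,ATT,0.99,0.35,0.4,0,0
S1_low_unequal,within,Psi,SN,0.35,0.99,0.32,0,0
S1_low_unequal,within,Psi,PBC,0.4,0.32,0.99,0,0
S1_low_unequal,within,Psi,INT,0,0,0,0.5,0
S1_low_unequal,within,Psi,BEH,0,0,0,0,0.68
S1_low_unequal,within,Sigma,ATT,0.99,0.35,0.4,0.61,0.25
S1_low_unequal,within,Sigma,SN,0.35,0.99,0.32,0.41,0.2
S1_low_unequal,within,Sigma,PBC,0.4,0.32,0.99,0.53,0.56
S1_low_unequal,within,Sigma,INT,0.61,0.41,0.53,0.99,0.35
S1_low_unequal,within,Sigma,BEH,0.25,0.2,0.56,0.35,1
S1_low_unequal,between,B,ATT,0,0,0,0,0
S1_low_unequal,between,B,SN,0,0,0,0,0
S1_low_unequal,between,B,PBC,0,0,0,0,0
S1_low_unequal,between,B,INT,-0.01,0.77,0.06,0,0
S1_low_unequal,between,B,BEH,0,0,0.02,0.59,0
S1_low_unequal,between,Psi,ATT,0.05,0.04,0.01,0,0
S1_low_unequal,between,Psi,SN,0.04,0.05,0.02,0,0
S1_low_unequal,between,Psi,PBC,0.01,0.02,0.05,0,0
S1_low_unequal,between,Psi,INT,0,0,0,0.02,0
S1_low_unequal,between,Psi,BEH,0,0,0,0,0.03
S1_low_unequal,between,Sigma,ATT,0.05,0.04,0.01,0.03,0.02
S1_low_unequal,between,Sigma,SN,0.04,0.05,0.02,0.04,0.02
S1_low_unequal,between,Sigma,PBC,0.01,0.02,0.05,0.02,0.01
S1_low_unequal,between,Sigma,INT,0.03,0.04,0.02,0.05,0.03
S1_low_unequal,between,Sigma,BEH,0.02,0.02,0.01,0.03,0.05
S2_medium_unequal,within,B,ATT,0,0,0,0,0
S2_medium_unequal,within,B,SN,0,0,0,0,0
S2_medium_unequal,within,B,PBC,0,0,0,0,0
S2_medium_unequal,within,B,INT,0.43,0.16,0.31,0,0
S2_medium_unequal,within,B,BEH,0,0,0.53,0.07,0
S2_medium_unequal,within,Psi,ATT,0.99,0.35,0.4,0,0
S2_medium_unequal,within,Psi,SN,0.35,0.99,0.32,0,0
S2_medium_unequal,within,Psi,PBC,0.4,0.32,0.99,0,0
S2_medium_unequal,within,Psi,INT,0,0,0,0.5,0
S2_medium_unequal,within,Psi,BEH,0,0,0,0,0.68
S2_medium_unequal,within,Sigma,ATT,0.99,0.35,0.4,0.61,0.25
S2_medium_unequal,within,Sigma,SN,0.35,0.99,0.32,0.41,0.2
S2_medium_unequal,within,Sigma,PBC,0.4,0.32,0.99,0.53,0.56
S2_medium_unequal,within,Sigma,INT,0.61,0.41,0.53,0.99,0.35
S2_medium_unequal,within,Sigma,BEH,0.25,0.2,0.56,0.35,1
S2_medium_unequal,between,B,ATT,0,0,0,0,0
S2_medium_unequal,between,B,SN,0,0,0,0,0
S2_medium_unequal,between,B,PBC,0,0,0,0,0
S2_medium_unequal,between,B,INT,-0.01,0.64,0.07,0,0
S2_medium_unequal,between,B,BEH,0,0,0.03,0.91,0
S2_medium_unequal,between,Psi,ATT,0.53,0.33,0.07,0,0
S2_medium_unequal,between,Psi,SN,0.33,0.41,0.13,0,0
S2_medium_unequal,between,Psi,PBC,0.07,0.13,0.22,0,0
S2_medium_unequal,between,Psi,INT,0,0,0,0.11,0
S2_medium_unequal,between,Psi,BEH,0,0,0,0,0.44
S2_medium_unequal,between,Sigma,ATT,0.53,0.33,0.07,0.21,0.19
S2_medium_unequal,between,Sigma,SN,0.33,0.41,0.13,0.27,0.25
S2_medium_unequal,between,Sigma,PBC,0.07,0.13,0.22,0.1,0.1
S2_medium_unequal,between,Sigma,INT,0.21,0.27,0.1,0.29,0.26
S2_medium_unequal,between,Sigma,BEH,0.19,0.25,0.1,0.26,0.68
S3_high_unequal,within,B,ATT,0,0,0,0,0
S3_high_unequal,within,B,SN,0,0,0,0,0
S3_high_unequal,within,B,PBC,0,0,0,0,0
S3_high_unequal,within,B,INT,0.43,0.16,0.31,0,0
S3_high_unequal,within,B,BEH,0,0,0.53,0.07,0
S3_high_unequal,within,Psi,ATT,0.99,0.35,0.4,0,0
S3_high_unequal,within,Psi,SN,0.35,0.99,0.32,0,0
S3_high_unequal,within,Psi,PBC,0.4,0.32,0.99,0,0
S3_high_unequal,within,Psi,INT,0,0,0,0.5,0
S3_high_unequal,within,Psi,BEH,0,0,0,0,0.68
S3_high_unequal,within,Sigma,ATT,0.99,0.35,0.4,0.61,0.25
S3_high_unequal,within,Sigma,SN,0.35,0.99,0.32,0.41,0.2
S3_high_unequal,within,Sigma,PBC,0.4,0.32,0.99,0.53,0.56
S3_high_unequal,within,Sigma,INT,0.61,0.41,0.53,0.99,0.35
S3_high_unequal,within,Sigma,BEH,0.25,0.2,0.56,0.35,1
S3_high_unequal,between,B,ATT,0,0,0,0,0
S3_high_unequal,between,B,SN,0,0,0,0,0
S3_high_unequal,between,B,PBC,0,0,0,0,0
S3_high_unequal,between,B,INT,-0.01,0.77,0.06,0,0
S3_high_unequal,between,B,BEH,0,0,0.02,0.59,0
S3_high_unequal,between,Psi,ATT,0.99,0.7,0.2,0,0
S3_high_unequal,between,Psi,SN,0.7,0.99,0.43,0,0
S3_high_unequal,between,Psi,PBC,0.2,0.43,0.99,0,0
S3_high_unequal,between,Psi,INT,0,0,0,0.38,0
S3_high_unequal,between,Psi,BEH,0,0,0,0,0.65
S3_high_unequal,between,Sigma,ATT,0.99,0.7,0.2,0.54,0.32
S3_high_unequal,between,Sigma,SN,0.7,0.99,0.43,0.77,0.47
S3_high_unequal,between,Sigma,PBC,0.2,0.43,0.99,0.39,0.25
S3_high_unequal,between,Sigma,INT,0.54,0.77,0.39,0.99,0.59
S3_high_unequal,between,Sigma,BEH,0.32,0.47,0.25,0.59,1
S4_high_equal,within,B,ATT,0,0,0,0,0
S4_high_equal,within,B,SN,0,0,0,0,0
S4_high_equal,within,B,PBC,0,0,0,0,0
S4_high_equal,within,B,INT,0.43,0.16,0.31,0,0
S4_high_equal,within,B,BEH,0,0,0.53,0.07,0
S4_high_equal,within,Psi,ATT,0.99,0.35,0.4,0,0
S4_high_equal,within,Psi,SN,0.35,0.99,0.32,0,0
S4_high_equal,within,Psi,PBC,0.4,0.32,0.99,0,0
S4_high_equal,within,Psi,INT,0,0,0,0.5,0
S4_high_equal,within,Psi,BEH,0,0,0,0,0.68
S4_high_equal,within,Sigma,ATT,0.99,0.35,0.4,0.61,0.25
S4_high_equal,within,Sigma,SN,0.35,0.99,0.32,0.41,0.2
S4_high_equal,within,Sigma,PBC,0.4,0.32,0.99,0.53,0.56
S4_high_equal,within,Sigma,INT,0.61,0.41,0.53,0.99,0.35
S4_high_equal,within,Sigma,BEH,0.25,0.2,0.56,0.35,1
S4_high_equal,between,B,ATT,0,0,0,0,0
S4_high_equal,between,B,SN,0,0,0,0,0
S4_high_equal,between,B,PBC,0,0,0,0,0
S4_high_equal,between,B,INT,0.43,0.16,0.31,0,0
S4_high_equal,between,B,BEH,0,0,0.53,0.07,0
S4_high_equal,between,Psi,ATT,0.99,0.35,0.4,0,0
S4_high_equal,between,Psi,SN,0.35,0.99,0.32,0,0
S4_high_equal,between,Psi,PBC,0.4,0.32,0.99,0,0
S4_high_equal,between,Psi,INT,0,0,0,0.5,0
S4_high_equal,between,Psi,BEH,0,0,0,0,0.68
S4_high_equal,between,Sigma,ATT,0.99,0.35,0.4,0.61,0.25
S4_high_equal,between,Sigma,SN,0.35,0.99,0.32,0.41,0.2
S4_high_equal,between,Sigma,PBC,0.4,0.32,0.99,0.53,0.56
S4_high_equal,between,Sigma,INT,0.61,0.41,0.53,0.99,0.35
S4_high_equal,between,Sigma,BEH,0.25,0.2,0.56,0.35,1
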