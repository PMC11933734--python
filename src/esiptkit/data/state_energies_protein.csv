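conformation_id,dE1,dE2,dE3,d_N_HO
1A,3.98,—,—,4.50
1B,3.84,—,—,4.50
2A,3.17,-0.03,2.28,2.94
2B,3.81,-0.50,2.68,2.61
3A,3.56,—,—,4.50
3B,3.70,—,—,4.50
EQ,3.37,-0.43,2.43,2.30
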