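analyte,h0,ce_opt_ev,b_ce,b_cece,b_cid,b_cidcid
PGE2-d4,55000,20,0.000000,-1.400000,0.000000,0.000000
LXA4-d5,23000,16,-2.200000,-2.200000,0.080000,0.000000
LTB4-d4,85000,18,-0.900000,-1.800000,0.000000,0.000000
9-HODE-d4,130000,22,0.800000,-1.600000,0.000000,0.000000
5-HETE-d8,150000,14,-3.000000,-2.000000,-0.080000,0.000000
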