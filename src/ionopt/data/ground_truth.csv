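analyte,h0,b_c,b_t,b_v,b_cc,b_tt,b_vv,b_ct,b_tv,inert_HG,inert_DG,inert_HB,inert_DL,width
PGE2-d4,60000,0.136302,0.142543,-0.120000,-0.089508,-0.142244,-0.060000,0.000000,0.000000,0.002,-0.001,0.0015,-0.001,3.2
LXA4-d5,25000,0.136304,0.111300,-0.120000,-0.089509,-0.065430,-0.060000,0.000000,0.040000,-0.0015,0.002,-0.001,0.0015,2.8
LTB4-d4,90000,0.144698,0.022061,-0.060000,-0.202180,-0.073001,-0.030000,0.147915,0.000000,0.001,0.0015,-0.002,0.001,3.5
9-HODE-d4,140000,0.255098,0.020312,-0.060000,-0.261421,-0.072265,-0.030000,0.136792,0.000000,-0.002,-0.0015,0.001,-0.0015,4.0
5-HETE-d8,160000,-0.032048,0.110274,-0.060000,-0.300000,-0.042415,-0.030000,0.000000,0.000000,0.0015,-0.001,-0.0015,0.002,3.8
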