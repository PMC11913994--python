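analyte,loq_pre_pg,loq_post_pg,snr_pre,snr_post
20-OH-LTB4,0.5,0.5,5.9,17.2
TXB2,1,0.5,5.2,12.5
PGF2a,2,1,8.1,11.7
PGE2,1,0.5,8.9,12.4
PGD2,1,1,12.8,15.7
LXA4,1,1,5.7,10.1
RvD5,1,0.5,5.2,11.5
t-LTB4,1,0.5,10.8,30.2
LTB4,1,0.5,7.1,24.7
13-HoTrE,4,2,5.8,14.6
9-HODE,1,1,15.6,32.7
15-HETE,2,1,6.9,25.9
12-HETE,2,0.5,8.9,36.7
5-HETE,1,0.24,8.9,44.2
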