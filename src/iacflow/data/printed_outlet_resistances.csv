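case,artery,resistance_mmhg_per_kg_s,mass_flow_0d_1e6_kg_s,rate_0d_pct,mass_flow_no0d_1e6_kg_s,rate_no0d_pct
A,ICA,17790,0,0,0,0
A,SThA,386370,0,0,0,0
A,LA,276843,0,0,0.2,1.5
A,OA,320828,0,0,0.1,0.8
A,FA,139474,9.2,69.7,12.6,95.5
A,MA,313216,4.0,30.3,0.3,2.3
B,ICA,19432,0,0,0,0
B,SThA,293588,0,0,0,0
B,LA,121408,7.5,56.8,11.1,84.1
B,OA,155639,0,0,0.1,0.8
B,FA,98513,1.6,12.1,1.4,10.6
B,PAA,508917,0.3,2.3,0.2,1.5
B,MA,105510,0.3,2.3,0.4,3.0
B,MMA,1742672,3.5,26.5,0,0
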