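case,vertical_class,position,model,la_label,oa_label,fa_label,artery,mass_flow_1e6_kg_s,rate_pct
A,1,C,A1-C,C,C,C,ICA,0,0
A,1,P1,A1-LA(F),F,R,L,ICA,0,0
A,1,P2,A1-LA(L),L,F,B,ICA,0,0
A,1,P3,A1-LA(R),R,B,F,ICA,0,0
A,1,P4,A1-LA(B),B,L,R,ICA,0,0
A,2,C,A2-C,C,C,C,ICA,0,0
A,2,P1,A2-LA(F),F,R,L,ICA,0,0
A,2,P2,A2-LA(L),L,F,B,ICA,0,0
A,2,P3,A2-LA(R),R,B,F,ICA,0,0
A,2,P4,A2-LA(B),B,L,R,ICA,0,0
A,3,C,A3-C,C,C,C,ICA,0,0
A,3,P1,A3-LA(F),F,R,L,ICA,0,0
A,3,P2,A3-LA(L),L,F,B,ICA,0,0
A,3,P3,A3-LA(R),R,B,F,ICA,0,0
A,3,P4,A3-LA(B),B,L,R,ICA,0,0
A,4,S,A4,S,S,S,ICA,0,0
A,1,C,A1-C,C,C,C,SThA,0,0
A,1,P1,A1-LA(F),F,R,L,SThA,0,0
A,1,P2,A1-LA(L),L,F,B,SThA,0,0
A,1,P3,A1-LA(R),R,B,F,SThA,0,0
A,1,P4,A1-LA(B),B,L,R,SThA,0,0
A,2,C,A2-C,C,C,C,SThA,0,0
A,2,P1,A2-LA(F),F,R,L,SThA,0,0
A,2,P2,A2-LA(L),L,F,B,SThA,0,0
A,2,P3,A2-LA(R),R,B,F,SThA,0,0
A,2,P4,A2-LA(B),B,L,R,SThA,0,0
A,3,C,A3-C,C,C,C,SThA,0,0
A,3,P1,A3-LA(F),F,R,L,SThA,0,0
A,3,P2,A3-LA(L),L,F,B,SThA,0,0
A,3,P3,A3-LA(R),R,B,F,SThA,0,0
A,3,P4,A3-LA(B),B,L,R,SThA,0,0
A,4,S,A4,S,S,S,SThA,0,0
A,1,C,A1-C,C,C,C,LA,0,0
A,1,P1,A1-LA(F),F,R,L,LA,9.8,74.2
A,1,P2,A1-LA(L),L,F,B,LA,0,0
A,1,P3,A1-LA(R),R,B,F,LA,0,0
A,1,P4,A1-LA(B),B,L,R,LA,0,0
A,2,C,A2-C,C,C,C,LA,0,0
A,2,P1,A2-LA(F),F,R,L,LA,0,0
A,2,P2,A2-LA(L),L,F,B,LA,0,0
A,2,P3,A2-LA(R),R,B,F,LA,0,0
A,2,P4,A2-LA(B),B,L,R,LA,0,0
A,3,C,A3-C,C,C,C,LA,0,0
A,3,P1,A3-LA(F),F,R,L,LA,0,0
A,3,P2,A3-LA(L),L,F,B,LA,0,0
A,3,P3,A3-LA(R),R,B,F,LA,0,0
A,3,P4,A3-LA(B),B,L,R,LA,0,0
A,4,S,A4,S,S,S,LA,13.2,100.0
A,1,C,A1-C,C,C,C,OA,0,0
A,1,P1,A1-LA(F),F,R,L,OA,0,0
A,1,P2,A1-LA(L),L,F,B,OA,4.6,34.8
A,1,P3,A1-LA(R),R,B,F,OA,0,0
A,1,P4,A1-LA(B),B,L,R,OA,0,0
A,2,C,A2-C,C,C,C,OA,0,0
A,2,P1,A2-LA(F),F,R,L,OA,0,0
A,2,P2,A2-LA(L),L,F,B,OA,10.4,78.8
A,2,P3,A2-LA(R),R,B,F,OA,0,0
A,2,P4,A2-LA(B),B,L,R,OA,0,0
A,3,C,A3-C,C,C,C,OA,0.1,0.8
A,3,P1,A3-LA(F),F,R,L,OA,0,0
A,3,P2,A3-LA(L),L,F,B,OA,0,0
A,3,P3,A3-LA(R),R,B,F,OA,0,0
A,3,P4,A3-LA(B),B,L,R,OA,0,0
A,4,S,A4,S,S,S,OA,0,0
A,1,C,A1-C,C,C,C,FA,9.2,69.7
A,1,P1,A1-LA(F),F,R,L,FA,3.4,25.8
A,1,P2,A1-LA(L),L,F,B,FA,0.3,2.3
A,1,P3,A1-LA(R),R,B,F,FA,13.1,99.2
A,1,P4,A1-LA(B),B,L,R,FA,10.4,78.8
A,2,C,A2-C,C,C,C,FA,6.5,49.2
A,2,P1,A2-LA(F),F,R,L,FA,13.0,98.5
A,2,P2,A2-LA(L),L,F,B,FA,0.3,2.3
A,2,P3,A2-LA(R),R,B,F,FA,12.6,95.5
A,2,P4,A2-LA(B),B,L,R,FA,12.8,97.0
A,3,C,A3-C,C,C,C,FA,10.6,80.3
A,3,P1,A3-LA(F),F,R,L,FA,12.9,97.7
A,3,P2,A3-LA(L),L,F,B,FA,0,0
A,3,P3,A3-LA(R),R,B,F,FA,13.2,100.0
A,3,P4,A3-LA(B),B,L,R,FA,7.3,55.3
A,4,S,A4,S,S,S,FA,0,0
A,1,C,A1-C,C,C,C,MA,4.0,30.3
A,1,P1,A1-LA(F),F,R,L,MA,0,0
A,1,P2,A1-LA(L),L,F,B,MA,8.3,62.9
A,1,P3,A1-LA(R),R,B,F,MA,0.1,0.8
A,1,P4,A1-LA(B),B,L,R,MA,2.8,21.2
A,2,C,A2-C,C,C,C,MA,6.7,50.8
A,2,P1,A2-LA(F),F,R,L,MA,0.3,2.3
A,2,P2,A2-LA(L),L,F,B,MA,2.5,18.9
A,2,P3,A2-LA(R),R,B,F,MA,0.6,4.5
A,2,P4,A2-LA(B),B,L,R,MA,0.3,2.3
A,3,C,A3-C,C,C,C,MA,2.6,19.7
A,3,P1,A3-LA(F),F,R,L,MA,0.4,3.0
A,3,P2,A3-LA(L),L,F,B,MA,13.2,100.0
A,3,P3,A3-LA(R),R,B,F,MA,0.1,0.8
A,3,P4,A3-LA(B),B,L,R,MA,5.9,44.7
A,4,S,A4,S,S,S,MA,0,0
B,1,C,B1-C,C,C,C,ICA,0,0
B,1,P1,B1-LA(F),F,L,B,ICA,0,0
B,1,P2,B1-LA(L),L,B,R,ICA,0,0
B,1,P3,B1-LA(R),R,F,L,ICA,0,0
B,1,P4,B1-LA(B),B,R,F,ICA,0,0
B,2,C,B2-C,C,C,C,ICA,0,0
B,2,P1,B2-LA(F),F,L,B,ICA,0,0
B,2,P2,B2-LA(L),L,B,R,ICA,0,0
B,2,P3,B2-LA(R),R,F,L,ICA,0,0
B,2,P4,B2-LA(B),B,R,F,ICA,0,0
B,3,C,B3-C,C,C,C,ICA,0,0
B,3,P1,B3-LA(F),F,L,B,ICA,0,0
B,3,P2,B3-LA(L),L,B,R,ICA,0,0
B,3,P3,B3-LA(R),R,F,L,ICA,0,0
B,3,P4,B3-LA(B),B,R,F,ICA,0,0
B,4,S,B4,S,S,S,ICA,0,0
B,1,C,B1-C,C,C,C,SThA,0,0
B,1,P1,B1-LA(F),F,L,B,SThA,0,0
B,1,P2,B1-LA(L),L,B,R,SThA,0,0
B,1,P3,B1-LA(R),R,F,L,SThA,0,0
B,1,P4,B1-LA(B),B,R,F,SThA,0,0
B,2,C,B2-C,C,C,C,SThA,0,0
B,2,P1,B2-LA(F),F,L,B,SThA,0,0
B,2,P2,B2-LA(L),L,B,R,SThA,0,0
B,2,P3,B2-LA(R),R,F,L,SThA,0,0
B,2,P4,B2-LA(B),B,R,F,SThA,0,0
B,3,C,B3-C,C,C,C,SThA,0,0
B,3,P1,B3-LA(F),F,L,B,SThA,0,0
B,3,P2,B3-LA(L),L,B,R,SThA,0,0
B,3,P3,B3-LA(R),R,F,L,SThA,0,0
B,3,P4,B3-LA(B),B,R,F,SThA,0,0
B,4,S,B4,S,S,S,SThA,0,0
B,1,C,B1-C,C,C,C,LA,7.5,56.8
B,1,P1,B1-LA(F),F,L,B,LA,13.2,100.0
B,1,P2,B1-LA(L),L,B,R,LA,13.2,100.0
B,1,P3,B1-LA(R),R,F,L,LA,0,0
B,1,P4,B1-LA(B),B,R,F,LA,0,0
B,2,C,B2-C,C,C,C,LA,0,0
B,2,P1,B2-LA(F),F,L,B,LA,0,0
B,2,P2,B2-LA(L),L,B,R,LA,0,0
B,2,P3,B2-LA(R),R,F,L,LA,0,0
B,2,P4,B2-LA(B),B,R,F,LA,0,0
B,3,C,B3-C,C,C,C,LA,0,0
B,3,P1,B3-LA(F),F,L,B,LA,0,0
B,3,P2,B3-LA(L),L,B,R,LA,0,0
B,3,P3,B3-LA(R),R,F,L,LA,0,0
B,3,P4,B3-LA(B),B,R,F,LA,0,0
B,4,S,B4,S,S,S,LA,13.2,100.0
B,1,C,B1-C,C,C,C,OA,0,0
B,1,P1,B1-LA(F),F,L,B,OA,0,0
B,1,P2,B1-LA(L),L,B,R,OA,0,0
B,1,P3,B1-LA(R),R,F,L,OA,5.6,42.4
B,1,P4,B1-LA(B),B,R,F,OA,0,0
B,2,C,B2-C,C,C,C,OA,0,0
B,2,P1,B2-LA(F),F,L,B,OA,0,0
B,2,P2,B2-LA(L),L,B,R,OA,0,0
B,2,P3,B2-LA(R),R,F,L,OA,2.5,18.9
B,2,P4,B2-LA(B),B,R,F,OA,0.1,0.8
B,3,C,B3-C,C,C,C,OA,0,0
B,3,P1,B3-LA(F),F,L,B,OA,0,0
B,3,P2,B3-LA(L),L,B,R,OA,0,0
B,3,P3,B3-LA(R),R,F,L,OA,0,0
B,3,P4,B3-LA(B),B,R,F,OA,0,0
B,4,S,B4,S,S,S,OA,0,0
B,1,C,B1-C,C,C,C,FA,1.6,12.1
B,1,P1,B1-LA(F),F,L,B,FA,0,0
B,1,P2,B1-LA(L),L,B,R,FA,0,0
B,1,P3,B1-LA(R),R,F,L,FA,7.3,55.3
B,1,P4,B1-LA(B),B,R,F,FA,12.1,91.7
B,2,C,B2-C,C,C,C,FA,7.0,53.0
B,2,P1,B2-LA(F),F,L,B,FA,1.8,13.6
B,2,P2,B2-LA(L),L,B,R,FA,5.9,44.7
B,2,P3,B2-LA(R),R,F,L,FA,8.6,65.2
B,2,P4,B2-LA(B),B,R,F,FA,11.2,84.8
B,3,C,B3-C,C,C,C,FA,9.6,72.7
B,3,P1,B3-LA(F),F,L,B,FA,1.6,12.1
B,3,P2,B3-LA(L),L,B,R,FA,12.8,97.0
B,3,P3,B3-LA(R),R,F,L,FA,13.1,99.2
B,3,P4,B3-LA(B),B,R,F,FA,13.0,98.5
B,4,S,B4,S,S,S,FA,0,0
B,1,C,B1-C,C,C,C,PAA,0.3,2.3
B,1,P1,B1-LA(F),F,L,B,PAA,0,0
B,1,P2,B1-LA(L),L,B,R,PAA,0,0
B,1,P3,B1-LA(R),R,F,L,PAA,0.2,1.5
B,1,P4,B1-LA(B),B,R,F,PAA,0,0
B,2,C,B2-C,C,C,C,PAA,0.1,0.8
B,2,P1,B2-LA(F),F,L,B,PAA,0,0
B,2,P2,B2-LA(L),L,B,R,PAA,0,0
B,2,P3,B2-LA(R),R,F,L,PAA,0.1,0.8
B,2,P4,B2-LA(B),B,R,F,PAA,0,0
B,3,C,B3-C,C,C,C,PAA,0,0
B,3,P1,B3-LA(F),F,L,B,PAA,0,0
B,3,P2,B3-LA(L),L,B,R,PAA,0,0
B,3,P3,B3-LA(R),R,F,L,PAA,0,0
B,3,P4,B3-LA(B),B,R,F,PAA,0,0
B,4,S,B4,S,S,S,PAA,0,0
B,1,C,B1-C,C,C,C,MA,0.3,2.3
B,1,P1,B1-LA(F),F,L,B,MA,0,0
B,1,P2,B1-LA(L),L,B,R,MA,0,0
B,1,P3,B1-LA(R),R,F,L,MA,0,0
B,1,P4,B1-LA(B),B,R,F,MA,0.4,3.0
B,2,C,B2-C,C,C,C,MA,0.8,6.1
B,2,P1,B2-LA(F),F,L,B,MA,0.4,3.0
B,2,P2,B2-LA(L),L,B,R,MA,1.7,12.9
B,2,P3,B2-LA(R),R,F,L,MA,0.3,2.3
B,2,P4,B2-LA(B),B,R,F,MA,0.7,5.3
B,3,C,B3-C,C,C,C,MA,0.8,6.1
B,3,P1,B3-LA(F),F,L,B,MA,1.2,9.1
B,3,P2,B3-LA(L),L,B,R,MA,0,0
B,3,P3,B3-LA(R),R,F,L,MA,0,0
B,3,P4,B3-LA(B),B,R,F,MA,0,0
B,4,S,B4,S,S,S,MA,0,0
B,1,C,B1-C,C,C,C,MMA,3.5,26.5
B,1,P1,B1-LA(F),F,L,B,MMA,0,0
B,1,P2,B1-LA(L),L,B,R,MMA,0,0
B,1,P3,B1-LA(R),R,F,L,MMA,0.2,1.5
B,1,P4,B1-LA(B),B,R,F,MMA,0.8,6.1
B,2,C,B2-C,C,C,C,MMA,5.3,40.2
B,2,P1,B2-LA(F),F,L,B,MMA,11.0,83.3
B,2,P2,B2-LA(L),L,B,R,MMA,5.7,43.2
B,2,P3,B2-LA(R),R,F,L,MMA,1.7,12.9
B,2,P4,B2-LA(B),B,R,F,MMA,1.4,10.6
B,3,C,B3-C,C,C,C,MMA,2.8,21.2
B,3,P1,B3-LA(F),F,L,B,MMA,10.5,79.5
B,3,P2,B3-LA(L),L,B,R,MMA,0.4,3.0
B,3,P3,B3-LA(R),R,F,L,MMA,0.1,0.8
B,3,P4,B3-LA(B),B,R,F,MMA,0.2,1.5
B,4,S,B4,S,S,S,MMA,0,0
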