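id,age,sex,weight_kg,height_m,disease_duration_y,updrs_motor,dled_mg,side_affected
1,67,M,61,1.68,5,32,300,L
2,76,F,80,1.68,5,28,300,L
3,73,M,74,1.78,10,41,400,L
4,65,M,64,1.65,2.5,23,100,R
5,66,M,73,1.75,4,45,850,R
6,63,M,70,1.66,6,35,450,L
7,63,F,75,1.66,3,28,450,L
8,67,F,66,1.57,6,26,1100,L
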