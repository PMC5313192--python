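x,y,b0,b1,se_b0,se_b1,r2,df
TL,FL,-1.12,0.85,0.71,0.00,0.96,1390
TL,PCL,-6.37,0.79,0.96,0.01,0.93,1115
FL,TL,7.67,1.13,0.79,0.01,0.96,1390
FL,PCL,-1.74,0.91,0.88,0.01,0.93,1114
PCL,TL,17.88,1.17,1.06,0.01,0.93,1115
PCL,FL,9.78,1.03,0.89,0.01,0.93,1114
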