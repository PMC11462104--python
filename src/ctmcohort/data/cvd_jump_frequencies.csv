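state,MI,Stroke,Death,CHF,CHMI,CHST,Angina,CHANMI,ANMI,CHAN
MI,0,1,44,31,0,2,7,1,0,0
Stroke,10,0,74,18,2,9,3,6,7,2
Death,0,0,0,0,0,0,0,0,0,0
CHF,14,25,101,0,3,0,11,13,9,11
CHMI,0,1,8,6,0,0,2,0,0,1
CHST,1,6,3,4,0,0,0,0,0,0
Angina,9,11,12,39,1,1,0,7,7,14
CHANMI,7,4,10,19,1,0,13,0,4,4
ANMI,3,4,4,15,0,0,16,6,0,3
CHAN,1,2,6,19,2,0,8,5,1,0
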