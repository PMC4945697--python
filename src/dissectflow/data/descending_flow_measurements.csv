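location,lumen,mean_flow_mm3_s
proximal,TL,15100
proximal,FL,40600
proximal,total,55600
medial,TL,11100
medial,FL,42500
medial,total,53800
distal,TL,7900
distal,FL,42400
distal,total,50300
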