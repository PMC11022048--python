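ion,z,c_in_mM,c_out_mM
Na+,1,13,142
Cl-,-1,5,120
K+,1,150,4
Ca++,2,0.0001,1
Mg++,2,1,0.5
HCO3-,-1,8,27
Organic anions,-1,155,0
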