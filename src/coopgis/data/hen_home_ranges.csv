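animal_id,age_wk,range_m2,prop_room,prop_overlap
B01,48,4.82,0.17,0.97
B01,66,1.65,0.06,1
B02,48,1.52,0.05,1
B02,66,7.64,0.27,0.94
B05,48,6,0.22,0.89
B05,66,9.11,0.33,0.84
B08,48,6.83,0.25,0.94
B08,66,7.68,0.28,0.85
B10,48,11.28,0.41,0.76
B10,66,1.66,0.06,0.99
Y05,48,2.97,0.11,1
Y05,66,0.37,0.01,1
Y07,48,2.8,0.1,0.9
Y07,66,1.82,0.07,0.76
Y08,48,10.04,0.36,0.5
Y08,66,13.35,0.48,0.27
Y10,48,3.14,0.11,0.96
Y10,66,3.26,0.12,0.9
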