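pair,overlap_48wk_m2,overlap_66wk_m2
B10-B01,4.39,0.51
B10-B02,1.49,1.53
B10-B05,5.09,1.59
B10-B08,6.21,1.15
B01-B02,1.27,1.64
B01-B05,3.65,1.64
B01-B08,3.10,1.57
B02-B05,1.09,6.57
B02-B08,1.43,5.49
B05-B08,2.98,5.87
Y05-Y07,0.08,1.01
Y05-Y08,0.33,2.87
Y05-Y10,0.03,2.07
Y07-Y08,1.37,2.48
Y07-Y10,0.77,1.22
Y08-Y10,2.88,2.88
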