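animal_id,age_wk,feed,drink,preen,dust_bathe,forage,rest,other
B01,48,40.62,0.00,8.59,0.00,16.03,1.78,32.97
B01,66,22.00,6.48,7.93,2.61,15.62,2.87,42.49
B10,48,12.10,2.69,19.36,0.18,15.47,1.98,48.23
B10,66,2.91,3.42,1.44,0.00,2.79,0.00,89.44
B02,48,31.46,1.85,12.15,2.73,9.51,11.09,31.21
B02,66,17.07,3.87,12.91,1.69,17.48,1.95,45.04
B05,48,32.35,4.92,9.18,2.32,15.11,4.22,31.90
B05,66,20.77,3.79,9.66,1.33,17.03,1.93,45.49
B08,48,1.71,3.54,19.82,2.63,22.45,14.14,35.71
B08,66,0.45,3.09,15.39,2.18,27.53,0.00,51.36
Y10,48,17.28,4.27,7.72,0.00,20.77,6.55,43.40
Y10,66,10.41,6.22,21.36,4.22,19.14,4.89,33.77
Y05,48,18.45,2.19,16.78,1.80,17.68,0.75,42.34
Y05,66,24.10,2.46,16.02,4.31,8.00,4.06,41.05
Y07,48,0.09,1.44,5.45,0.00,0.00,0.00,93.02
Y07,66,0.03,1.33,2.58,0.00,0.00,0.00,96.06
Y08,48,1.33,2.68,18.75,0.24,30.05,3.39,43.57
Y08,66,7.46,2.27,23.29,0.00,19.01,11.55,36.42
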