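patient_id,R0_mm,v_mm_per_yr,k_mm,tau_yr,tmin_yr
0,17.95,0.50,7.29,1.98,3.95
1,29.03,1.33,10.49,0.19,0.72
2,24.56,3.24,17.69,1.40,1.91
3,16.86,0.96,13.28,1.57,3.42
4,25.40,1.11,5.20,0.10,0.39
5,28.72,1.37,10.78,0.47,1.33
6,27.00,1.99,17.00,2.39,3.04
7,23.26,1.23,5.92,1.18,1.66
8,15.83,2.45,6.84,0.45,0.82
9,31.60,1.13,8.35,0.38,1.12
10,26.45,4.00,16.15,0.45,0.98
11,14.67,1.54,4.66,0.32,0.72
12,41.20,4.00,30.74,1.83,2.63
13,16.64,3.59,13.83,1.06,1.37
14,20.21,1.30,14.84,3.64,4.16
15,19.33,0.70,7.80,0.81,2.11
16,23.61,3.37,23.15,2.28,2.51
17,32.68,0.72,7.30,0.43,1.36
18,35.02,2.19,15.32,0.99,1.93
19,28.06,0.52,10.16,1.29,3.52
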