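subject,marker_id,angle_deg,distance_ratio
1,p_e1,45.98,0.7623
1,p_e3,66.13,0.7306
1,p_e2,45.00,0.5742
1,p_e4,66.16,0.5998
1,p_m1,131.44,0.7348
1,p_m2,130.03,0.7378
1,p_m3,91.21,0.3582
1,p_m4,90.65,0.3549
2,p_e1,44.13,0.6985
2,p_e3,64.67,0.7051
2,p_e2,44.36,0.5298
2,p_e4,64.50,0.5413
2,p_m1,129.23,0.6989
2,p_m2,129.54,0.6941
2,p_m3,89.57,0.3173
2,p_m4,89.25,0.3188
3,p_e1,45.06,0.7374
3,p_e3,66.00,0.7607
3,p_e2,46.06,0.5673
3,p_e4,66.03,0.5768
3,p_m1,130.97,0.7368
3,p_m2,130.63,0.7731
3,p_m3,90.08,0.3548
3,p_m4,91.02,0.3347
4,p_e1,44.98,0.7042
4,p_e3,64.05,0.6755
4,p_e2,44.60,0.5358
4,p_e4,64.01,0.5344
4,p_m1,129.20,0.7230
4,p_m2,129.26,0.6857
4,p_m3,89.34,0.3267
4,p_m4,89.67,0.3170
5,p_e1,45.09,0.7495
5,p_e3,65.72,0.7287
5,p_e2,45.85,0.5910
5,p_e4,65.16,0.5839
5,p_m1,131.00,0.7610
5,p_m2,130.05,0.7603
5,p_m3,90.55,0.3598
5,p_m4,90.73,0.3358
6,p_e1,44.97,0.7114
6,p_e3,64.77,0.6913
6,p_e2,44.99,0.5519
6,p_e4,64.92,0.5114
6,p_m1,129.34,0.7261
6,p_m2,129.42,0.7012
6,p_m3,89.67,0.3153
6,p_m4,89.41,0.2900
7,p_e1,46.16,0.7334
7,p_e3,65.37,0.7297
7,p_e2,46.10,0.5581
7,p_e4,65.79,0.6048
7,p_m1,130.86,0.7400
7,p_m2,130.20,0.7564
7,p_m3,91.39,0.3333
7,p_m4,90.54,0.3569
8,p_e1,44.88,0.7087
8,p_e3,64.44,0.6914
8,p_e2,44.11,0.5215
8,p_e4,64.96,0.5227
8,p_m1,129.84,0.7284
8,p_m2,129.65,0.7329
8,p_m3,89.58,0.3327
8,p_m4,89.02,0.2970
9,p_e1,45.42,0.7280
9,p_e3,65.45,0.7645
9,p_e2,45.81,0.5840
9,p_e4,65.95,0.5767
9,p_m1,130.79,0.7439
9,p_m2,131.07,0.7780
9,p_m3,90.83,0.3683
9,p_m4,90.03,0.3367
10,p_e1,44.09,0.6983
10,p_e3,64.42,0.7136
10,p_e2,44.84,0.5076
10,p_e4,64.36,0.5181
10,p_m1,129.80,0.7027
10,p_m2,129.89,0.7172
10,p_m3,89.72,0.2831
10,p_m4,89.58,0.2922
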