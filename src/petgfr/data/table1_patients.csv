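patient_id,sex,age_years,bsa_m2,therapy,creatinine_mg_dl,hct,activity_pet_mbq,scinti_tracer,activity_scinti_mbq
1,f,53,1.88,DOTATOC,0.89,0.39,137,MAG3,75
2,m,72,2.08,DOTATOC,1.41,0.32,109,DTPA,148
3,f,58,1.56,DOTATOC,0.60,0.31,112,MAG3,74
4,m,78,1.91,DOTATOC,0.85,0.40,102,DTPA,141
5,m,67,1.98,DOTATOC,0.99,0.39,79,DTPA,155
6,m,67,2.18,DOTATOC,1.26,0.35,94,DTPA,152
7,m,70,1.81,PSMA,0.92,0.35,112,DTPA,130
8,m,46,2.25,DOTATOC,0.90,0.40,120,MAG3,66
9,m,65,1.98,PSMA,0.88,0.26,113,DTPA,135
10,m,79,1.95,PSMA,1.15,0.38,120,MAG3,69
11,m,72,1.77,PSMA,0.66,0.29,119,DTPA,159
12,m,79,1.96,PSMA,0.95,0.29,125,DTPA,136
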