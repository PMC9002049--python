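patient_id,gfr_ckd,gfr_pet30,gfr_pet30_wo2to10,gfr_pet15,gfr_pet15_wo2to10
1,80.6,72.9,71.0,68.8,68.9
2,59.4,46.9,43.7,45.2,43.3
3,90.9,82.0,76.6,79.3,75.0
4,92.2,89.1,73.7,89.4,72.0
5,89.8,84.1,63.7,88.4,64.9
6,73.8,85.5,63.7,88.4,74.3
7,87.9,84.0,88.6,83.0,87.9
8,132.8,128.9,107.6,122.8,104.9
9,103.1,56.2,62.3,61.1,62.8
10,67.9,41.3,49.0,41.4,49.2
11,98.8,91.7,79.6,90.7,79.9
12,85.9,70.3,52.0,74.4,66.6
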