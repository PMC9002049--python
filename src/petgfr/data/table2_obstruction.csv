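patient_id,interval_days,pet_result,scintigraphy_result
1,-57,no urinary obstruction,no urinary obstruction
2,-113,no urinary obstruction,no urinary obstruction
3,-3,no urinary obstruction,no urinary obstruction
4,46,no urinary obstruction,no urinary obstruction
5,40,no urinary obstruction,no urinary obstruction
6,84,no urinary obstruction,no urinary obstruction
7,21,no urinary obstruction,no urinary obstruction
8,85,no urinary obstruction,no urinary obstruction
9,29,both-sided urinary obstruction,both-sided urinary obstruction
10,-71,right-sided urinary obstruction,right-sided urinary obstruction
11,126,no urinary obstruction,no urinary obstruction
12,15,both-sided urinary obstruction,both-sided urinary obstruction
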