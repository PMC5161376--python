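age_low,age_high,sex,utility
18,25,male,0.950
18,25,female,0.940
25,35,male,0.940
25,35,female,0.930
35,45,male,0.920
35,45,female,0.910
45,55,male,0.880
45,55,female,0.860
55,65,male,0.840
55,65,female,0.810
65,75,male,0.800
65,75,female,0.760
75,120,male,0.740
75,120,female,0.690
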