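age_lo,rr_per_2e,ln_rr_sd
20,1.23,0.05
25,1.23,0.05
30,1.23,0.05
35,1.23,0.05
40,1.23,0.05
45,1.23,0.05
50,1.23,0.05
55,1.23,0.05
60,1.23,0.05
65,1.23,0.05
70,1.23,0.05
75,1.23,0.05
80,1.23,0.05
85,1.23,0.05
90,1.23,0.05
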