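age_band,weight
0-4,12000
5-9,10000
10-14,9000
15-19,9000
20-24,8000
25-29,8000
30-34,6000
35-39,6000
40-44,6000
45-49,6000
50-54,5000
55-59,4000
60-64,4000
65-69,3000
70-74,2000
75-79,1000
80-84,500
85+,500
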