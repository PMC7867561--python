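subject_id,explained_variance_pct
1,38.08
2,13.44
3,44.32
4,25.54
5,13.14
6,7.22
7,10.25
8,1.78
9,35.28
10,50.95
11,25.25
12,43.86
13,20.08
14,37.83
15,30.3
16,27.59
17,11.42
18,11.02
19,27.87
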