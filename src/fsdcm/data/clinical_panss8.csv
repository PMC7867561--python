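subject_id,p1,p2,p3,n1,n4,n6,g5,g9,panss_positive,panss_negative,panss8_total,medication,dup_months
1,4,4,4,4,5,3,2,4,12,12,30,0,24
2,5,4,5,2,3,1,3,4,14,6,27,0,4
3,4,5,4,5,4,3,1,3,13,12,29,1,1
4,5,1,5,3,4,3,1,4,11,10,26,0,2
5,5,3,4,2,3,3,1,3,12,8,24,1,2
6,5,1,5,3,5,3,3,2,11,11,27,0,9
7,6,5,6,1,1,1,4,5,17,3,29,0,12
8,5,4,4,2,4,2,1,4,13,8,26,0,19
9,7,3,5,4,3,1,2,6,15,8,31,1,59
10,6,4,2,1,1,1,1,3,12,3,19,1,3
11,6,3,2,1,1,1,1,4,11,3,19,0,14
12,4,2,5,3,1,2,1,3,11,6,21,1,
13,5,6,5,1,3,4,3,5,16,8,32,0,6
14,5,4,2,1,1,1,1,5,11,3,20,1,1
15,7,4,6,1,1,1,1,6,17,3,27,0,
16,5,1,5,4,3,1,1,3,11,8,23,0,9
17,7,3,2,5,4,3,1,3,12,12,28,0,72
18,5,1,5,1,5,1,1,3,11,7,22,1,1
19,5,3,1,3,3,3,1,4,9,9,23,1,1
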