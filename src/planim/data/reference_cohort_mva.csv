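exam,mva_cm2
1,4.2
2,5.3
3,5.1
4,4.0
5,5.5
6,4.9
7,7.4
8,4.5
9,2.7
10,1.6
11,1.6
12,1.8
13,3.7
14,2.6
15,3.2
16,1.6
17,1.0
18,1.1
19,1.0
20,1.1
21,0.7
22,0.9
23,0.5
24,0.4
25,0.6
26,0.4
27,0.7
28,0.6
29,0.7
30,0.7
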