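count
8
16
15
24
26
26
38
43
46
45
57
64
65
73
73
86
89
97
108
97
146
121
143
142
105
98
136
114
118
109
97
150
71
52
29
44
47
35
42
31
38
31
30
28
27
22
17
22
11
7
13
10
14
13
11
8
3
7
6
9
7
4
6
5
3
5
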