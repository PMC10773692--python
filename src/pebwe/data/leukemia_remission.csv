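time,event
1,1
1,1
2,1
4,1
4,1
6,1
6,1
6,1
7,1
8,1
9,1
9,1
10,1
12,1
13,1
14,1
18,1
19,1
24,1
26,1
29,1
31,0
42,1
45,0
50,0
57,1
60,1
71,0
85,0
91,1
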