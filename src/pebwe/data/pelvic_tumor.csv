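time,event
3,1
7,1
11,0
18,1
22,0
25,1
28,1
32,0
34,0
35,1
35,0
36,0
40,0
40,0
41,1
54,0
66,0
76,0
84,0
88,0
92,0
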