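case,slice1,slice2,slice3,slice4,slice5
1,yes,yes,yes,yes,yes
2,yes,yes,yes,yes,no
3,yes,yes,yes,yes,yes
4,yes,yes,yes,yes,yes
5,yes,yes,yes,yes,no
6,no,no,no,no,no
7,no,no,no,no,no
8,no,no,no,no,no
9,no,yes,yes,no,yes
10,no,no,yes,yes,yes
11,no,no,no,yes,no
12,no,no,no,yes,yes
13,no,no,no,yes,yes
14,no,yes,yes,no,yes
15,yes,no,no,yes,yes
16,no,no,yes,no,no
17,no,yes,no,yes,yes
18,no,no,no,yes,no
19,no,yes,no,yes,no
20,no,yes,yes,no,yes
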