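number,control,test
1,95.8,89.4
2,89.4,91.9
3,82.9,94.8
4,94.4,93.1
5,82.5,93.6
6,72.8,96.8
7,93.6,91.1
8,74.0,96.0
9,87.4,92.2
10,84.8,91.8
11,78.6,92.8
12,80.1,92.6
13,96.8,95.5
14,84.6,93.7
15,88.6,89.4
16,77.0,92.6
17,94.7,92.2
18,89.4,93.9
19,94.5,94.6
20,74.9,91.3
21,83.3,93.5
22,88.4,94.5
23,74.6,92.2
24,84.6,89.9
25,84.9,89.4
26,85.4,92.6
27,85.3,95.5
28,78.8,95.5
29,75.8,91.2
30,72.6,96.9
31,82.4,92.4
32,78.0,92.5
33,87.5,89.3
34,75.1,92.5
35,90.4,89.6
36,83.6,92.1
37,96.3,96.1
38,86.4,93.2
39,72.2,94.8
40,92.8,92.1
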