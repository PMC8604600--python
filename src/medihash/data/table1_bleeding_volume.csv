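number,control,test
1,436.9,393.6
2,427.3,381.9
3,424.8,380.0
4,422.2,372.4
5,421.8,360.5
6,413.6,357.7
7,393.5,353.5
8,378.1,345.9
9,354.3,338.6
10,344.0,337.6
11,343.4,333.9
12,312.8,310.2
13,290.6,296.9
14,289.7,290.3
15,282.5,289.4
16,280.5,280.9
17,276.7,268.8
18,273.1,255.8
19,269.0,250.8
20,263.2,240.7
21,245.7,232.9
22,232.7,215.4
23,226.7,200.3
24,215.8,197.1
25,185.5,196.0
26,185.0,191.8
27,182.1,190.0
28,174.7,182.1
29,173.9,174.0
30,150.6,161.9
31,150.2,158.9
32,146.7,158.0
33,140.5,141.5
34,133.1,115.4
35,132.5,112.2
36,120.6,95.2
37,120.3,79.3
38,103.3,77.2
39,101.4,73.4
40,100.1,50.8
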