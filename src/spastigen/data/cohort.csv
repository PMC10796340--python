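ID,Type,Age,Height,Mass,Tone,Upperarm,Forearm,Hands
1,Caucasian Male,23,179.6,50,50,28.5,28.62,21.3
2,Caucasian Female,23,164.9,50,50,29.38,24.24,18.35
3,African Male,23,181.4,50,50,28.76,28.96,21.54
4,African Female,23,166.4,50,50,29.49,24.33,18.41
5,Asian Male,23,171.46,50,50,27.15,27.05,20.23
6,Asian Female,23,158.52,50,50,28.25,23.31,17.83
7,Latino Male,33,182.6,50,50,29.04,29.12,21.37
8,Latino Female,33,161.3,50,50,28.78,23.65,17.74
9,Caucasian Male,23,179.6,75,50,28.26,29.32,21.44
10,Caucasian Female,23,164.9,75,50,30.17,24.65,18.39
11,African Male,23,181.4,75,50,28.5,29.73,21.67
12,African Female,23,166.4,75,50,30.28,24.74,18.45
13,Asian Male,23,171.46,75,50,26.98,27.83,20.37
14,Asian Female,23,158.52,75,50,29.04,23.73,17.69
15,Caucasian Male,23,179.6,75,25,28.32,30.03,21.3
16,Caucasian Female,23,164.9,75,25,31.32,23.76,18.36
17,African Male,23,181.4,75,25,28.55,30.37,21.53
18,African Female,23,166.4,75,25,31.42,23.85,18.42
19,Asian Male,23,171.46,75,25,27.05,28.48,20.23
20,Asian Female,23,158.52,75,25,30.18,22.84,17.66
21,Caucasian Male,23,179.6,25,75,28.58,28.53,21.29
22,Caucasian Female,23,164.9,25,75,29.46,24.19,18.34
23,African Male,23,181.4,25,75,28.84,28.87,21.52
24,African Female,23,166.4,25,75,29.57,24.28,18.4
25,Asian Male,23,171.46,25,75,27.23,26.96,20.22
26,Asian Female,23,158.52,25,75,28.33,23.26,17.64
27,Caucasian Male,23,179.6,50,75,28.36,28.73,21.43
28,Caucasian Female,23,164.9,50,75,29.3,24.81,18.38
29,African Male,23,181.4,50,75,28.61,29.07,21.67
30,African Female,23,166.4,50,75,29.4,24.9,18.45
31,Asian Male,23,171.46,50,75,27.03,27.16,20.37
32,Asian Female,23,158.52,50,75,28.16,23.89,17.69
33,Caucasian Male,68,178.1,50,50,28.79,28.79,20.95
34,Caucasian Female,68,163.3,50,50,29.62,24.12,18.17
35,African Male,68,179.9,50,50,29.05,29.14,21.18
36,African Female,68,164.81,50,50,29.72,24.2,18.23
37,Asian Male,68,169.95,50,50,27.45,27.22,19.88
38,Asian Female,68,156.94,50,50,28.48,23.19,17.47
39,Caucasian Male,68,178.1,75,50,28.58,29.58,21.07
40,Caucasian Female,68,163.3,75,50,30.54,24.29,18.21
41,African Male,68,179.9,75,50,28.82,29.92,21.31
42,African Female,68,164.81,75,50,30.65,24.37,18.27
43,Asian Male,68,169.95,75,50,27.28,28.02,20
44,Asian Female,68,156.94,75,50,29.41,23.36,17.51
45,Caucasian Male,68,178.1,75,25,28.63,30.03,20.96
46,Caucasian Female,68,163.3,75,25,31.42,23.77,18.18
47,African Male,68,179.9,75,25,28.86,30.37,21.2
48,African Female,68,164.81,75,25,31.53,23.85,18.25
49,Asian Male,68,169.95,75,25,27.38,28.48,19.89
50,Asian Female,68,156.94,75,25,30.29,22.84,17.49
51,Caucasian Male,68,178.1,25,75,28.83,28.53,20.95
52,Caucasian Female,68,163.3,25,75,29.52,24.19,18.17
53,African Male,68,179.9,25,75,29.09,28.87,21.19
54,African Female,68,164.81,25,75,29.62,24.28,18.23
55,Asian Male,68,169.95,25,75,27.48,26.96,19.88
56,Asian Female,68,156.94,25,75,28.38,23.26,17.47
57,Caucasian Male,68,178.1,50,75,28.8,28.76,21.11
58,Caucasian Female,68,163.3,50,75,29.09,24.79,18.21
59,African Male,68,179.9,50,75,29.06,29.1,21.34
60,African Female,68,164.81,50,75,29.2,24.88,18.27
61,Asian Male,68,169.95,50,75,27.46,27.19,20.04
62,Asian Female,68,156.94,50,75,27.96,23.86,17.51
63,Caucasian Male,48,180.49,50,50,28.92,28.95,21.16
64,Caucasian Female,48,165.51,50,50,29.77,24.35,18.3
65,African Male,48,182.27,50,50,29.18,29.3,21.39
66,African Female,48,167.01,50,50,29.87,24.43,18.36
67,Asian Male,48,172.33,50,50,27.57,27.38,20.09
68,Asian Female,48,159.14,50,50,28.63,23.42,17.6
69,Caucasian Male,48,180.49,75,50,28.68,29.77,21.29
70,Caucasian Female,48,165.51,75,50,30.77,24.64,18.34
71,African Male,48,182.27,75,50,28.92,30.11,21.53
72,African Female,48,167.01,75,50,30.75,24.72,18.41
73,Asian Male,48,172.33,75,50,27.39,28.2,20.22
74,Asian Female,48,159.14,75,50,29.51,23.71,17.65
75,Caucasian Male,48,180.49,75,25,28.74,30.3,21.17
76,Caucasian Female,48,165.51,75,25,28.57,23.97,18.32
77,African Male,48,182.27,75,25,28.97,30.64,21.41
78,African Female,48,167.01,75,25,31.75,24.05,18.38
79,Asian Male,48,172.33,75,25,27.48,28.74,20.1
80,Asian Female,48,159.14,75,25,30.51,23.04,17.62
81,Caucasian Male,48,180.49,25,75,28.96,28.8,21.16
82,Caucasian Female,48,165.51,25,75,29.74,24.39,18.3
83,African Male,48,182.27,25,75,29.23,29.14,21.4
84,African Female,48,167.01,25,75,29.84,24.48,18.36
85,Asian Male,48,172.33,25,75,27.62,27.22,20.1
86,Asian Female,48,159.14,25,75,28.6,23.46,17.6
87,Caucasian Male,48,180.49,50,75,28.82,28.99,21.31
88,Caucasian Female,48,165.51,50,75,29.48,24.98,18.34
89,African Male,48,182.27,50,75,29.08,29.33,21.54
90,African Female,48,167.01,50,75,29.59,25.06,18.4
91,Asian Male,48,172.33,50,75,27.49,27.42,20.24
92,Asian Female,48,159.14,50,75,28.34,24.05,17.64
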