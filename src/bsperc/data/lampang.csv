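29
30
28
30
27
21
19
33
39
32
37
33
30
27
32
41
43
39
41
40
44
50
49
57
60
59
71
62
59
67
88
87
80
82
68
52
40
39
65
106
108
113
125
158
211
153
42
23
19
27
57
67
74
72
88
92
59
96
143
155
150
138
132
119
100
84
90
97
101
99
103
64
49
48
53
41
51
34
32
39
42
51
62
129
119
99
121
94
103
148
148
86
64
92
172
185
182
113
80
72
96
133
130
100
122
119
82
89
91
93
91
60
55
37
61
48
30
38
44
34
36
63
32
37
48
52
51
46
17
19
21
20
16
17
22
23
23
35
33
31
36
27
24
23
29
31
28
34
25
22
18
18.6
17.4
20.3
20.6
16.1
16.8
16.7
14.9
16.5
19.2
20.4
21.6
18.7
16.91
8.2
16.3
16
14.8
15.6
14.8
13.5
13.3
14.7
12.8
13
12.5
12.7
14.4
13
12.7
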