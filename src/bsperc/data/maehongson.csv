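25
21
19
18
18
20
16
23
25
26
20
18
17
21
27
28
24
28
27
28
25
21
26
30
36
38
40
42
41
35
40
41
47
42
41
34
30
31
37
39
54
64
78
69
57
70
68
13
9
15
21
27
28
34
36
48
59
66
75
78
79
92
97
103
104
91
91
111
118
142
216
134
53
59
62
60
98
116
104
148
137
144
255
309
244
237
209
263
321
256
233
144
109
147
176
204
203
147
117
108
124
119
104
106
166
214
138
61
59
56
53
50
38
34
34
49
39
36
50
49
34
23
23
22
28
29
31
26
13
18
8
8
5
11
12
13
17
18
19
19
21
19
19
15
17
17
16
17
13
10
11
8.3
11.6
13.3
10.3
6.2
5.5
5.8
7.1
14.1
13.5
15.2
10
10.1
10.2
10.2
9
5.5
3.7
3.7
3.9
3.6
3.3
4.2
4.2
4.4
4.4
5
5.5
4.8
7.1
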