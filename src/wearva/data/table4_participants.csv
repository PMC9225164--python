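participant_id,gender,age,va_events,fitbit_days,device_type
1,Male,67,6,193,ICD
2,Male,61,0,966,Not specified
3,Male,41,0,120,Not specified
4,Male,55,1,960,ICD
5,Male,66,6,364,ICD
6,Male,67,0,79,Not specified
7,Male,28,1,65,ICD
8,Male,69,0,567,Not specified
9,Male,47,1,519,ICD
10,Male,61,0,261,Not specified
11,Male,59,5,60,ICD
12,Male,66,23,647,CRT-D
13,Male,58,5,357,CRT-D
14,Male,67,1,317,ICD
15,Male,56,6,332,ICD
16,Female,52,11,980,ICD
17,Female,61,0,99,Not specified
18,Male,47,20,326,ICD
19,Male,45,45,450,ICD
20,Male,67,127,801,ICD
21,Male,66,0,148,Not specified
22,Male,69,1,395,ICD
23,Male,38,0,98,Not specified
24,Male,59,0,136,Not specified
25,Male,51,3,842,ICD
26,Male,49,0,891,Not specified
27,Male,74,0,796,Not specified
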