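patient_id,agree,differ
1,5,2
2,5,2
3,4,3
4,3,4
5,6,1
6,6,1
7,3,4
8,4,3
9,2,5
10,5,2
11,5,2
12,4,3
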