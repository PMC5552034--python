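id,age,pre,post,followup
1,7,1,4,
2,7,3,5,
3,9,1,5,6
4,11,5,6,5
5,12,4,6,
6,12,6,6,7
7,12,6,6,
8,13,4,6,
9,16,5,6,
10,19,4,5,
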