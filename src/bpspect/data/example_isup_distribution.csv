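isup_grade,patients
0,17
1,14
2,5
3,3
4,1
5,2
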