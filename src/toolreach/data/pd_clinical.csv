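id,sex,age,education,duration,updrs,hy_stage,side
1,F,72,5,6,37,3,L
2,M,76,5,5,28,2,R
3,M,56,8,5,28,2,L
4,F,72,13,6,43,3,L
5,F,75,8,6,12,1,L
6,M,63,5,9,57,4,L
7,F,74,11,11,22,2,R
8,M,68,8,7,41,2,R
9,F,56,13,8,31,2,R
10,F,77,13,4,21,2,L
11,M,54,13,6,19,2,L
12,F,67,5,17,27,2,L
13,F,57,13,9,13,2,R
14,F,69,13,8,46,3,R
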