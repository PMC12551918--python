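X1,X2,X3,X4,X5
1.0,0.9931,0.9865,0.9866,0.9872
0.9931,1.0,0.9611,0.9975,0.976
0.9865,0.9611,1.0,0.9469,0.986
0.9866,0.9975,0.9469,1.0,0.9589
0.9872,0.976,0.986,0.9589,1.0
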