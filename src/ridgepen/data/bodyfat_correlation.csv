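X1,X2,X3,X4,X5,X6,X7,X8,X9,X10,X11,X12,X13
1.0,0.9412,0.9069,0.859,0.8091,0.4774,0.7922,0.5437,0.8114,0.7415,0.9349,0.4897,-0.7334
0.9412,1.0,0.9505,0.9156,0.8528,0.4214,0.8016,0.5447,0.7968,0.7195,0.9521,0.5309,-0.8134
0.9069,0.9505,1.0,0.9289,0.9076,0.4926,0.8359,0.5411,0.8088,0.7873,0.9648,0.5844,-0.7429
0.859,0.9156,0.9289,1.0,0.858,0.4354,0.8756,0.5897,0.7993,0.7222,0.9102,0.4506,-0.7684
0.8091,0.8528,0.9076,0.858,1.0,0.5116,0.8066,0.5576,0.757,0.7302,0.9054,0.6871,-0.6475
0.4774,0.4214,0.4926,0.4354,0.5116,1.0,0.4899,0.3635,0.4906,0.5619,0.535,0.5184,-0.2328
0.7922,0.8016,0.8359,0.8756,0.8066,0.4899,1.0,0.7029,0.8514,0.7483,0.8752,0.5428,-0.6402
0.5437,0.5447,0.5411,0.5897,0.5576,0.3635,0.7029,1.0,0.6884,0.5604,0.6484,0.4592,-0.4322
0.8114,0.7968,0.8088,0.7993,0.757,0.4906,0.8514,0.6884,1.0,0.8236,0.8865,0.5748,-0.5422
0.7415,0.7195,0.7873,0.7222,0.7302,0.5619,0.7483,0.5604,0.8236,1.0,0.8311,0.5935,-0.3969
0.9349,0.9521,0.9648,0.9102,0.9054,0.535,0.8752,0.6484,0.8865,0.8311,1.0,0.6662,-0.7278
0.4897,0.5309,0.5844,0.4506,0.6871,0.5184,0.5428,0.4592,0.5748,0.5935,0.6662,1.0,-0.3928
-0.7334,-0.8134,-0.7429,-0.7684,-0.6475,-0.2328,-0.6402,-0.4322,-0.5422,-0.3969,-0.7278,-0.3928,1.0
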