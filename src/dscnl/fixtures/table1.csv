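dataset,stage,class1,class2,class3,class4,class5,class6,class7,class8,class9
BloodMNIST,before,852,2181,1085,2026,849,993,2330,1643,
BloodMNIST,after,1073,1956,1239,1843,1074,1140,2023,1611,
PathMNIST,before,9366,9509,10360,10401,8006,12182,7886,9401,12885
PathMNIST,after,9601,9496,10196,10380,8637,11479,8592,9698,11917
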