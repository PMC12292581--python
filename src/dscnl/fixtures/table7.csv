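task,class1,class2,class3,class4,class5,class6,class7,class8,mean_purity
1,98.0,96.8,,,,,,,97.4
2,96.8,98.4,94.4,94.4,,,,,96
3,96.42,100,92.85,94.04,94.04,82.5,,,93.3
4,95.23,100,90.47,93.65,92.06,85.71,100,100,94.64
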