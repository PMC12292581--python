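noise_rate,task1,task2,task3,task4,mean_purity
0.1,97.57,95.65,92.82,99.11,96.28
0.2,97.67,94.29,89.94,98.62,95.13
0.3,95.66,91.31,87.02,98.95,93.23
0.4,94.74,87.57,77.87,98.22,89.6
0.5,88.88,85.64,68.31,96.02,84.71
0.6,82.66,75.07,54.32,95.17,76.8
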