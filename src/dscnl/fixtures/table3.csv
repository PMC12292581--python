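method,after_task,task1,task2,task3,task4
Finetune,1,97.35,,,
Finetune,2,0,93.93,,
Finetune,3,0,0,95.64,
Finetune,4,0,0,0,98.24
SI,1,98.73,,,
SI,2,0,94.61,,
SI,3,0,0,95.26,
SI,4,0,0,0,99.12
ER,1,97.7,,,
ER,2,26.15,96.74,,
ER,3,0.46,1.01,95.83,
ER,4,0.23,0.11,0.57,99.21
DER,1,98.04,,,
DER,2,61.75,95.39,,
DER,3,64.17,73.37,87.29,
DER,4,44.12,65.17,29.79,85.92
AGEM,1,98.27,,,
AGEM,2,0.00,87.19,,
AGEM,3,0.00,0.00,96.77,
AGEM,4,0.00,0.00,0.00,98.77
DSCNL,1,99.08,,,
DSCNL,2,94.59,91.91,,
DSCNL,3,90.78,50.11,96.77,
DSCNL,4,93.55,50.57,92.22,99.65
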