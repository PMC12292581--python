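method,after_task,task1,task2,task3,task4
Finetune,1,97.76,,,
Finetune,2,0,82.22,,
Finetune,3,0,0,94.59,
Finetune,4,0,0,0,82.88
SI,1,94.46,,,
SI,2,0,84.79,,
SI,3,0,0,90.23,
SI,4,0,0,0,83.92
ER,1,97.66,,,
ER,2,1.98,77.34,,
ER,3,0.6,0.78,90.49,
ER,4,0,0,0,82.51
DER,1,98.81,,,
DER,2,41.81,95.09,,
DER,3,20.82,63.73,89.84,
DER,4,13.05,51.34,17.71,82.29
AGEM,1,97.93,,,
AGEM,2,96.51,0,,
AGEM,3,2.48,21.32,88.41,
AGEM,4,4.64,25.45,18.88,82.90
DSCNL,1,99.95,,,
DSCNL,2,97.84,97.32,,
DSCNL,3,63.79,77.46,93.03,
DSCNL,4,72.70,73.10,18.82,90.32
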