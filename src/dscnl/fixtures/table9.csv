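method,after_task,task1,task2,task3,task4
DER,1,98.04,,,
DER,2,61.75,95.39,,
DER,3,64.17,73.37,87.29,
DER,4,44.12,65.17,29.79,85.92
DSCNL (w.random),1,98.39,,,
DSCNL (w.random),2,92.97,84.04,,
DSCNL (w.random),3,56.34,49.66,97.15,
DSCNL (w.random),4,30.88,31.46,96.58,99.65
DSCNL (w.res),1,96.08,,,
DSCNL (w.res),2,97.47,88.88,,
DSCNL (w.res),3,85.60,47.87,96.96,
DSCNL (w.res),4,87.44,46.07,85.20,99.56
DSCNL (w.uncer),1,99.08,,,
DSCNL (w.uncer),2,94.59,91.91,,
DSCNL (w.uncer),3,90.78,50.11,96.77,
DSCNL (w.uncer),4,93.55,50.57,92.22,99.65
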