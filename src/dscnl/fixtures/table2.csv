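method,0.1,0.2,0.3,0.4,0.5,0.6
Finetune,24.95,24.86,24.55,24.2,23.54,22.88
SI,25,24.82,24.77,24.31,23.74,22.88
ER,37.41,29.75,25.02,24.49,23.48,23.39
DER,81.59,70.19,56.24,56.81,33.24,28.15
AGEM,24.88,24.03,24.69,23.59,23.56,22.33
DSCNL,86.16,82.47,84.02,79.09,73.51,69.72
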