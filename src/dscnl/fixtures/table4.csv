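method,0.1,0.2,0.3,0.4,0.5,0.6
Finetune,21.83,20.99,20.72,18.66,17.77,15.24
SI,21.99,20.74,20.98,18.68,17.3,15.55
ER,24.93,21.91,20.62,19.61,16.48,16.41
DER,54.21,43.49,41.09,38.96,23.62,20.83
AGEM,35.83,36.34,32.96,22.03,19.02,14.44
DSCNL,56.99,47.56,63.73,55.71,32.88,44.47
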