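method,0.1,0.2,0.3,0.4,0.5,0.6
DER,81.59,70.19,56.24,56.81,33.24,28.15
DSCNL (w.random),62.65,56.84,64.64,61.5,50.25,48.87
DSCNL (w.res),83.12,79.15,79.56,82.09,68.85,66.39
DSCNL (w.uncer),84.73,82.47,84.02,79.09,73.51,69.72
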