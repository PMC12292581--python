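buffer_size,0.1,0.2,0.3,0.4,0.5,0.6
200,76.86,67.93,68.51,68.79,64.17,46.50
500,84.73,82.47,84.02,79.09,73.51,69.72
1000,87.77,85.98,86.23,84.35,78.79,79.15
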