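buffer_size,0.1,0.2,0.3,0.4,0.5,0.6
200,56.29,37.41,37.46,33.91,30.72,24.13
500,56.99,47.56,63.73,55.71,33.80,43.21
1000,63.89,67.64,59.65,59.55,47.23,45.98
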