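trans_type,0.1,0.2,0.3,0.4,0.5,0.6
Affine Trans,85.69,76.86,78.96,76.52,71.54,65.93
Pixel Trans,84.77,80.30,80.57,74.68,63.77,54.71
Mix Trans,86.16,82.47,84.02,79.09,73.51,69.72
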