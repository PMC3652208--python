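class,sensitivity,specificity,accuracy
N,97.9,92.7,95.4
S,83.0,98.0,95.8
F,82.4,97.5,95.6
V,82.8,98.7,96.6
Q,83.9,97.9,96.0
Total,90.3,97.4,95.9
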