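true_class,cluster_1,cluster_2,cluster_3,cluster_4,cluster_5
N,803,15,12,13,16
S,27,191,0,0,0
V,35,0,164,0,0
F,17,0,0,178,0
Q,28,0,0,0,183
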