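record,N,S,V,F,Q
106,104,0,83,0,0
200,125,0,112,0,0
208,95,0,0,86,0
209,102,106,0,0,0
213,106,0,0,113,0
217,205,0,0,0,211
222,122,112,0,0,0
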