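type,benign,malignant
A,0,0
B,0,10
C,1,5
D,6,32
amputation,1,11
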