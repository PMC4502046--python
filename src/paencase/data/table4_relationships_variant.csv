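relationship,benign_obs1,benign_obs2,benign_final,malignant_obs1,malignant_obs2,malignant_final
encasement,4,8,8,56,59,58
displacement,1,2,2,28,25,27
penetration,15,10,10,4,4,4
in_margin,0,0,0,1,1,1
disconnection,3,3,3,2,2,2
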