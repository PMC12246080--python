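transcript,length_nt,n_pairs,covered_nt,percent
MT-ND1,954,7,322,34
MT-ND2,1041,9,417,40
MT-ND3,345,5,243,70
MT-ND4L,294,5,201,68
MT-ND4,1377,7,343,25
MT-ND5,1809,5,451,25
MT-ND6,522,3,137,26
MT-CO1,1539,15,696,45
MT-CO2,681,4,188,28
MT-CO3,783,5,221,28
Mt-co3 (rat),814,16,683,84
MT-ATP8,204,3,143,70
MT-ATP6,678,5,218,32
MT-CYB,1140,18,767,67
MT-CYB (rat),1157,22,954,82
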