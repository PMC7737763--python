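# synthetic rotamer central values
# residue,rotamer,mean1,sd1[,mean2,sd2,...]
LEU,rot1,124.97,13.19,50.30,8.64
LEU,rot2,14.81,14.10,2.80,10.53
LEU,rot3,35.35,10.71,-158.67,10.26
SER,rot1,143.00,13.43
SER,rot2,-98.93,10.10
SER,rot3,134.48,8.04
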