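system_id,method,neg_de_kjmol
alpha-PHB,adz-atz-fit,23.56
beta-PHB,adz-atz-fit,10.18
GGG,adz-atz-fit,8.95
GCGC,adz-atz-fit,56.79
C2C2PD,adz-atz-fit,87.81
alpha-PHB,atz-aqz-focal,24.03
beta-PHB,atz-aqz-focal,10.23
GGG,atz-aqz-focal,8.87
GCGC,atz-aqz-focal,56.44
C2C2PD,atz-aqz-focal,86.19
alpha-PHB,sapt-dft,26.14
beta-PHB,sapt-dft,11.43
GGG,sapt-dft,6.88
GCGC,sapt-dft,54.69
C2C2PD,sapt-dft,82.68
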