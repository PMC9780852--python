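system_id,subset,group_label,e_pol,e_exch,e_ind,e_disp,e_total,de_ref
aniline:methane,set3x6,dispersion_dominated,-6.5,18.9,-1.9,-17.3,-6.8,-6.84
anisole:methane,set3x6,dispersion_dominated,-7.1,19.9,-1.6,-18.5,-7.3,-7.39
1-Nap:methane,set3x6,dispersion_dominated,-9.0,25.3,-1.8,-23.4,-8.9,-9.14
1-Nap:CO,set3x6,dispersion_dominated,-9.4,24.0,-3.4,-20.2,-9.0,-8.37
1-Nap:CO2,set3x6,dispersion_dominated,-13.1,28.6,-3.2,-24.6,-12.3,-12.68
anisole:anisole,set3x6,dispersion_dominated,-32.8,72.8,-8.6,-57.6,-26.1,-27.16
anisole:ammonia,set3x6,mixed,-16.1,24.3,-3.7,-15.7,-11.2,-12.00
1-Nap:ethyne,set3x6,mixed,-25.1,35.0,-10.1,-17.4,-17.5,-16.96
HCl:HCl,set3x6,mixed,-11.3,17.6,-6.3,-9.2,-9.2,-7.94
benzene:water,set3x6,mixed,-13.5,19.2,-5.1,-14.7,-14.0,-13.43
anisole:CO2,set3x6,mixed,-20.5,28.6,-3.5,-18.8,-14.1,-15.86
ethyne:ethyne,set3x6,mixed,-9.0,11.6,-2.9,-6.9,-7.3,-6.26
1-Nap:ammonia,set3x6,electrostatics_dominated,-70.0,80.6,-28.7,-22.8,-40.9,-40.52
HCl:water,set3x6,electrostatics_dominated,-41.5,50.7,-17.6,-14.3,-22.8,-22.47
HCN:HF,set3x6,electrostatics_dominated,-42.6,42.9,-18.5,-11.8,-30.1,-31.09
NCH:FH,set3x6,electrostatics_dominated,-15.4,11.5,-3.4,-5.2,-12.4,-12.34
HCN:HCN,set3x6,electrostatics_dominated,-25.2,20.3,-6.8,-7.8,-19.5,-19.83
1-Nap:water,set3x6,electrostatics_dominated,-46.2,50.0,-15.8,-16.6,-28.6,-29.86
furan:toluene#1,furan_toluene,,-9.0,26.5,-2.9,-29.2,-14.5,-14.43
furan:toluene#2,furan_toluene,,-8.9,27.6,-3.1,-29.8,-14.2,-13.94
furan:toluene#3,furan_toluene,,-7.3,26.5,-2.8,-29.3,-12.9,-12.62
furan:toluene#4,furan_toluene,,-7.7,25.9,-3.1,-28.3,-13.2,-12.82
furan:toluene#5,furan_toluene,,-7.6,25.6,-2.8,-27.8,-12.5,-12.06
furan:toluene#6,furan_toluene,,-6.7,23.7,-2.6,-25.9,-11.5,-11.00
furan:toluene#7,furan_toluene,,-5.3,20.8,-2.2,-23.5,-10.1,-9.65
anthracene:cyclopropenium,misc,,-58.5,81.8,-60.3,-48.3,-85.3,-89.96
pyridine:pyridine,misc,,-12.0,28.2,-3.3,-29.8,-16.8,-15.82
alpha-PHB,large,,-14.7,17.5,-3.8,-25.1,-26.1,-24.03
beta-PHB,large,,-8.1,29.1,-4.0,-28.4,-11.4,-10.23
C2C2PD,large,,-37.1,114.3,-12.8,-147.1,-82.7,-87.82
GCGC,large,,-37.4,104.1,-9.5,-111.9,-54.7,-56.90
GGG,large,,11.3,27.8,-6.2,-39.9,-6.9,-8.79
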