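# Ion property table, v1. Sources: crystal (ionic) radii: Shannon (1976),
# Acta Cryst. A32, 751 (effective radii at the stated coordination number);
# viscosity B coefficients: Jenkins & Marcus (1995), Chem. Rev. 95, 2695;
# hydration free energies (-dG_hydr): Marcus (1991), J. Chem. Soc. Faraday
# Trans. 87, 2995; first-shell coordination numbers: Marcus (1988),
# Chem. Rev. 88, 1475 (representative values).
symbol,charge,crystal_radius_A,viscosity_B_cm3_mol,hydration_energy_kJ_mol,coordination_number,source
Na+,1,1.02,0.086,365,6,shannon1976/jenkins1995/marcus1991
Mg2+,2,0.72,0.385,1830,6,shannon1976/jenkins1995/marcus1991
Ca2+,2,1.00,0.285,1505,7,shannon1976/jenkins1995/marcus1991
Zn2+,2,0.74,0.369,1955,6,shannon1976/jenkins1995/marcus1991
Sr2+,2,1.18,0.261,1380,8,shannon1976/jenkins1995/marcus1991
Y3+,3,0.90,0.660,3450,8,shannon1976/jenkins1995/marcus1991
Ba2+,2,1.35,0.220,1250,9,shannon1976/jenkins1995/marcus1991
La3+,3,1.03,0.582,3145,9,shannon1976/jenkins1995/marcus1991
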