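# SAMPL8 CB[8] host-guest set: experimental binding free energies vs
# tight-binding calculated values (kcal/mol); top-ranked pose and
# Boltzmann-weighted ensemble flavors.
ligand_id,exp_dg,exp_unc,dg_top,dg_ens
G0,-14.67,0.1,-18.25,-18.25
G1,-7.05,0.1,-10.61,-12.22
G2,-9.94,0.06,-9.84,-11.14
G3,-11.6,0.04,-14.80,-16.31
G4,-11.2,0.1,-14.74,-16.13
G5,-12.3,0.16,-11.62,-12.95
G6,-14.1,0.04,-10.03,-11.30
G7,-7.93,0.15,-12.38,-13.54
G8,-9.18,0.03,-8.30,-7.90
G9,-10.2,0.04,-8.64,-8.13
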