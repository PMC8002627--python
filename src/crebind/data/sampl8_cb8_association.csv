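# Electronic energies of association E_a (kcal/mol) of the top-ranked
# CB[8]*G0-G9 complexes: tight-binding values vs DFT single points.
ligand_id,GFN2-xTB,PBE0,B2PLYP,PWPB95
G0,-38.61,-31.12,-37.68,-33.77
G1,-28.39,-19.57,-21.68,-19.66
G2,-30.34,-18.63,-23.20,-20.30
G3,-35.28,-22.31,-27.55,-24.42
G4,-35.79,-19.12,-24.51,-21.44
G5,-31.26,-22.57,-28.41,-25.15
G6,-28.31,-25.57,-29.70,-28.59
G7,-28.69,-11.53,-15.94,-12.96
G8,-22.46,-20.86,-21.69,-19.87
G9,-24.51,-22.37,-23.54,-21.44
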