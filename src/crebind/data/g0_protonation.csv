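# Calculated CB[8]*G0 binding free energies (kcal/mol) for the three
# candidate protonation states of the G0 ligand, against the single
# experimental value.
ligand_id,exp_dg,exp_unc,dg_top,dg_ens
G0_2plus,-14.67,0.1,-35.93,-37.30
G0_1plus,-14.67,0.1,-18.25,-20.02
G0_neutral,-14.67,0.1,-4.06,
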