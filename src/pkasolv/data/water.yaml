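# Neat water at 298.15 K; dG fields in kcal/mol, conc_SH in mol/L.
name: water
conc_SH: 55.5
pK_ap: 14.0
delta: 0.0
dG_gas_acid: 385.64
dG_gas_acid_sigma: 0.10
dG_gas_base: 159.64
dG_gas_base_sigma: 1.90
dG_sol_SH: -6.32
dG_sol_SH_sigma: 0.20
dG_sol_H: -265.90
dG_sol_H_sigma: 0.10
T: 298.15
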