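# Neat methanol at 298.15 K; dG fields in kcal/mol, conc_SH in mol/L.
# delta is the pH* - pH_app offset of the aqueous-calibrated meter scale.
name: methanol
conc_SH: 24.5
pK_ap: 16.7
delta: 2.30
dG_gas_acid: 377.93
dG_gas_acid_sigma: 0.62
dG_gas_base: 175.06
dG_gas_base_sigma: 1.90
dG_sol_SH: -4.86
dG_sol_SH_sigma: 0.20
dG_sol_H: -263.50
dG_sol_H_sigma: 2.00
T: 298.15
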