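# Experimental thermochemistry of neat solvents at 298.15 K.
# Units: conc_SH in mol/L; pK_ap and delta dimensionless; all dG fields in kcal/mol.
# Empty sigma cells mean the value is treated as exact.
name,conc_SH,pK_ap,pK_ap_sigma,delta,dG_gas_acid,dG_gas_acid_sigma,dG_gas_base,dG_gas_base_sigma,dG_sol_SH,dG_sol_SH_sigma,dG_sol_H,dG_sol_H_sigma,T
water,55.5,14.0,,0.0,385.64,0.10,159.64,1.90,-6.32,0.20,-265.90,0.10,298.15
methanol,24.5,16.7,,2.30,377.93,0.62,175.06,1.90,-4.86,0.20,-263.50,2.00,298.15
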