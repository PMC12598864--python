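# Absolute gas-phase free energies of the species in each solvent's
# heterolytic dissociation, in kcal/mol. Empty sigma cells mean exact.
solvent,species,G_gas,G_gas_sigma
water,SH,-47857.37,
water,SH2+,-48022.66,
water,S-,-47465.69,
methanol,SH,-72444.89,
methanol,SH2+,-72626.01,
methanol,S-,-72061.05,
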