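# United-atom OPLS methanol geometry placeholder: CO 1.43 A, OH 0.945 A,
# COH 108.5 deg. Coordinates in A, epsilon kcal/mol, sigma A, charge e.
name,x,y,z,epsilon,sigma,charge
CH3,1.43,0.0,0.0,0.207,3.775,0.265
O,0.0,0.0,0.0,0.170,3.070,-0.700
H,-0.29668,0.89615,0.0,0.0,0.0,0.435
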