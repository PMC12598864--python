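# SPC water sites: coordinates in A, epsilon kcal/mol, sigma A, charge e.
name,x,y,z,epsilon,sigma,charge
O,0.0,0.0,0.0,0.1554,3.165,-0.82
H1,0.8165,0.0,0.5774,0.0,0.0,0.41
H2,-0.8165,0.0,0.5774,0.0,0.0,0.41
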