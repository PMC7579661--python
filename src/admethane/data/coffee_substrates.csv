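name,N,C,H,S,O,TS,VS,HHV,annual_mass
pellets,3.2,50.6,6.5,0.1,39.6,93.9,86.1,13.9,
roasted_coffee_powder,3.1,54.2,6.9,0.0,35.9,97.4,92.8,12.8,
green_coffee_powder,2.6,50.3,6.4,0.0,40.8,90.7,84.4,19.9,
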