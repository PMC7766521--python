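# Component energies of the H/D binding cycle (kcal/mol): hydration and
# receptor-interaction legs for the protiated and deuterated states.
quantity	isotope	energy_kcal_mol
hydration	H	-71.63
hydration	D	-71.20
interaction	H	-82.31
interaction	D	-82.73
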