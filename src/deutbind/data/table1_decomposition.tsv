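# Per-residue MM-GBSA decomposition of the histamine binding free energy.
# total_dg_bind_kcal_mol=-14.2
residue	contribution_kcal_mol
Asp98	-5.45
Val99	-1.78
Phe254	-1.60
Thr103	-1.29
Phe251	-0.97
Thr190	-0.84
Tyr250	-0.83
Gly187	-0.64
Asp186	-0.64
Met100	-0.20
Glu270	-0.16
Cys102	-0.14
Glu267	-0.11
Val178	-0.10
Tyr94	-0.08
Val189	-0.08
Val185	-0.07
Val255	-0.06
Leu193	0.02
Gly157	0.02
Lys166	0.02
Lys83	0.02
Val273	0.02
Asn108	0.02
Lys88	0.02
Tyr192	0.03
Arg260	0.03
Ala253	0.05
Ser153	0.05
Arg161	0.06
Lys173	0.11
Gln177	0.11
Gly183	0.13
Arg257	0.15
Leu97	0.19
Lys175	0.29
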