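name	role	delta_total	delta_d	delta_p	delta_h	density	tg	tg_scale	molar_mass
GLB	drug	23.8				1.37	62	C	494.0
PVP K25	polymer	22.2				1.18	145	C
PVP VA64	polymer	23.7				1.167	101	C
SOL	polymer	22.1				0.99	71	C
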