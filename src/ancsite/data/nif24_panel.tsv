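# ancsite packaged panel: 24 substrate-channel sites of the nitrogenase D subunit
# columns: alignment column (1-based), corresponding Azotobacter vinelandii NifD residue,
# structural/functional role, conserved residue in the alignment (one-letter code)
column	reference_label	role	conserved_residue
182	alpha-70^Val	Modulates substrate access to catalytic core/active site	V
350	alpha-195^His	H-bond with FeMoCo, flexible (S2A or S2B)	H
497	alpha-281^Tyr	Substrate channel formation; gating residue	Y
493	alpha-277^Arg	H-bond with FeMoCo in substrate channel (surface flap for substrate access)	R
604	alpha-383^His	Substrate channel formation; gating residue	H
491	alpha-275^Cys	Coordinates FeMoCo	C
745	alpha-442^His	Coordinates FeMoCo	H
224	alpha-96^Arg	Coordinates FeMoCo	R
346	alpha-191^Gln	Coordinates FeMoCo	Q
181	alpha-69^Gly	Switch control for alpha-70^Val side chain	G
347	alpha-192^Ser	N2 interaction in substrate channel	S
155	alpha-49^Asn	Lines substrate channel	N
178	alpha-66^Gly	Lines substrate channel	G
183	alpha-71^Val	Lines substrate channel	V
345	alpha-190^Ser	Lines substrate channel	S
348	alpha-193^Leu	Lines substrate channel	L
351	alpha-196^His	Lines substrate channel	H
354	alpha-199^Asn	Lines substrate channel	N
494	alpha-278^Ser	Lines substrate channel	S
495	alpha-279^Met	Lines substrate channel	M
496	alpha-280^Asn	Lines substrate channel	N
576	alpha-357^Gly	Lines substrate channel	G
602	alpha-381^Phe	Lines substrate channel	F
603	alpha-382^Ala	Lines substrate channel	A
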