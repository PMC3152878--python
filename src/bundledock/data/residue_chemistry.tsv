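# residue_chemistry v1
# Residue chemistry tables consumed across the package.
# Columns: table <TAB> key <TAB> value
#
# polarity: three-way residue classification used for interface/surface
#   composition percentages. Convention: His counted charged, Gly polar.
# charge_atom: side-chain atoms carrying a formal charge class, "RES:ATOM" -> +/-
#   (His treated as positively charged for salt-bridge detection).
# vdw: van der Waals radius per element, Angstrom.
# one_letter: 3-letter -> 1-letter amino acid codes.
# donor / acceptor: heavy-atom hydrogen-bond roles, "RES:ATOM" (backbone
#   roles "*:N" donor and "*:O" acceptor apply to every residue but Pro N).
# max_sasa_sidechain: reference maximum side-chain accessible area per
#   residue (Angstrom^2, extended Gly-X-Gly type values) for relative
#   exposure; Gly entry is the whole-residue value.
polarity	ASP	charged
polarity	GLU	charged
polarity	LYS	charged
polarity	ARG	charged
polarity	HIS	charged
polarity	SER	polar
polarity	THR	polar
polarity	ASN	polar
polarity	GLN	polar
polarity	TYR	polar
polarity	CYS	polar
polarity	TRP	polar
polarity	GLY	polar
polarity	ALA	nonpolar
polarity	VAL	nonpolar
polarity	LEU	nonpolar
polarity	ILE	nonpolar
polarity	PRO	nonpolar
polarity	PHE	nonpolar
polarity	MET	nonpolar
charge_atom	ASP:OD1	-
charge_atom	ASP:OD2	-
charge_atom	GLU:OE1	-
charge_atom	GLU:OE2	-
charge_atom	LYS:NZ	+
charge_atom	ARG:NH1	+
charge_atom	ARG:NH2	+
charge_atom	ARG:NE	+
charge_atom	HIS:ND1	+
charge_atom	HIS:NE2	+
vdw	C	1.70
vdw	N	1.55
vdw	O	1.52
vdw	S	1.80
vdw	H	1.20
vdw	P	1.80
one_letter	ALA	A
one_letter	CYS	C
one_letter	ASP	D
one_letter	GLU	E
one_letter	PHE	F
one_letter	GLY	G
one_letter	HIS	H
one_letter	ILE	I
one_letter	LYS	K
one_letter	LEU	L
one_letter	MET	M
one_letter	ASN	N
one_letter	PRO	P
one_letter	GLN	Q
one_letter	ARG	R
one_letter	SER	S
one_letter	THR	T
one_letter	VAL	V
one_letter	TRP	W
one_letter	TYR	Y
donor	*:N	+
donor	SER:OG	+
donor	THR:OG1	+
donor	TYR:OH	+
donor	ASN:ND2	+
donor	GLN:NE2	+
donor	LYS:NZ	+
donor	ARG:NE	+
donor	ARG:NH1	+
donor	ARG:NH2	+
donor	HIS:ND1	+
donor	HIS:NE2	+
donor	TRP:NE1	+
acceptor	*:O	+
acceptor	ASP:OD1	+
acceptor	ASP:OD2	+
acceptor	GLU:OE1	+
acceptor	GLU:OE2	+
acceptor	ASN:OD1	+
acceptor	GLN:OE1	+
acceptor	SER:OG	+
acceptor	THR:OG1	+
acceptor	TYR:OH	+
acceptor	HIS:ND1	+
acceptor	HIS:NE2	+
max_sasa_sidechain	ALA	67.0
max_sasa_sidechain	ARG	196.0
max_sasa_sidechain	ASN	113.0
max_sasa_sidechain	ASP	106.0
max_sasa_sidechain	CYS	104.0
max_sasa_sidechain	GLN	144.0
max_sasa_sidechain	GLU	138.0
max_sasa_sidechain	GLY	80.0
max_sasa_sidechain	HIS	151.0
max_sasa_sidechain	ILE	140.0
max_sasa_sidechain	LEU	137.0
max_sasa_sidechain	LYS	167.0
max_sasa_sidechain	MET	160.0
max_sasa_sidechain	PHE	175.0
max_sasa_sidechain	PRO	105.0
max_sasa_sidechain	SER	80.0
max_sasa_sidechain	THR	102.0
max_sasa_sidechain	TRP	217.0
max_sasa_sidechain	TYR	187.0
max_sasa_sidechain	VAL	117.0
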