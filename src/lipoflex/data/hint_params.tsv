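res_name	atom_name	a	polarity_class	hbond_role
*	C	-0.3	polar-neutral	none
*	CA	0.1	hydrophobic	none
*	H	-0.1	polar-neutral	none
*	H1	-0.1	polar-neutral	none
*	H2	-0.1	polar-neutral	none
*	H3	-0.1	polar-neutral	none
*	HA	0.1	hydrophobic	none
*	HA1	0.1	hydrophobic	none
*	HA2	0.1	hydrophobic	none
*	N	-0.6	polar-neutral	donor
*	O	-0.8	polar-neutral	acceptor
*	OXT	-1.1	acid	acceptor
ALA	CB	0.5	hydrophobic	none
ARG	CB	0.5	hydrophobic	none
ARG	CD	0.1	hydrophobic	none
ARG	CG	0.5	hydrophobic	none
ARG	CZ	-0.3	polar-neutral	none
ARG	HD1	0.1	hydrophobic	none
ARG	HD2	0.1	hydrophobic	none
ARG	HE	-0.1	base	none
ARG	HH11	-0.1	base	none
ARG	HH12	-0.1	base	none
ARG	HH21	-0.1	base	none
ARG	HH22	-0.1	base	none
ARG	NE	-1.0	base	donor
ARG	NH1	-1.0	base	donor
ARG	NH2	-1.0	base	donor
ASN	CB	0.5	hydrophobic	none
ASN	CG	-0.3	polar-neutral	none
ASN	HD21	-0.1	polar-neutral	none
ASN	HD22	-0.1	polar-neutral	none
ASN	ND2	-0.7	polar-neutral	donor
ASN	OD1	-0.8	polar-neutral	acceptor
ASP	CB	0.5	hydrophobic	none
ASP	CG	-0.3	polar-neutral	none
ASP	OD1	-1.1	acid	acceptor
ASP	OD2	-1.1	acid	acceptor
CYS	CB	0.1	hydrophobic	none
CYS	HB1	0.1	hydrophobic	none
CYS	HB2	0.1	hydrophobic	none
CYS	HG	-0.1	polar-neutral	none
CYS	SG	-0.2	polar-neutral	both
GLN	CB	0.5	hydrophobic	none
GLN	CD	-0.3	polar-neutral	none
GLN	CG	0.5	hydrophobic	none
GLN	HE21	-0.1	polar-neutral	none
GLN	HE22	-0.1	polar-neutral	none
GLN	NE2	-0.7	polar-neutral	donor
GLN	OE1	-0.8	polar-neutral	acceptor
GLU	CB	0.5	hydrophobic	none
GLU	CD	-0.3	polar-neutral	none
GLU	CG	0.5	hydrophobic	none
GLU	OE1	-1.1	acid	acceptor
GLU	OE2	-1.1	acid	acceptor
HIS	CB	0.5	hydrophobic	none
HIS	CD2	0.1	hydrophobic	none
HIS	CE1	0.1	hydrophobic	none
HIS	CG	0.1	hydrophobic	none
HIS	HD2	0.1	hydrophobic	none
HIS	HE1	0.1	hydrophobic	none
HIS	HE2	-0.1	polar-neutral	none
HIS	ND1	-0.5	amphoteric	acceptor
HIS	NE2	-0.5	amphoteric	donor
ILE	CB	0.5	hydrophobic	none
ILE	CD1	0.5	hydrophobic	none
ILE	CG1	0.5	hydrophobic	none
ILE	CG2	0.5	hydrophobic	none
LEU	CB	0.5	hydrophobic	none
LEU	CD1	0.5	hydrophobic	none
LEU	CD2	0.5	hydrophobic	none
LEU	CG	0.5	hydrophobic	none
LYS	CB	0.5	hydrophobic	none
LYS	CD	0.5	hydrophobic	none
LYS	CE	0.1	hydrophobic	none
LYS	CG	0.5	hydrophobic	none
LYS	HE1	0.1	hydrophobic	none
LYS	HE2	0.1	hydrophobic	none
LYS	HZ1	-0.1	base	none
LYS	HZ2	-0.1	base	none
LYS	HZ3	-0.1	base	none
LYS	NZ	-1.2	base	donor
MET	CB	0.5	hydrophobic	none
MET	CE	0.1	hydrophobic	none
MET	CG	0.1	hydrophobic	none
MET	HE1	0.1	hydrophobic	none
MET	HE2	0.1	hydrophobic	none
MET	HE3	0.1	hydrophobic	none
MET	HG1	0.1	hydrophobic	none
MET	HG2	0.1	hydrophobic	none
MET	SD	0.3	hydrophobic	none
PHE	CB	0.5	hydrophobic	none
PHE	CD1	0.3	hydrophobic	none
PHE	CD2	0.3	hydrophobic	none
PHE	CE1	0.3	hydrophobic	none
PHE	CE2	0.3	hydrophobic	none
PHE	CG	0.3	hydrophobic	none
PHE	CZ	0.3	hydrophobic	none
PHE	HD1	0.1	hydrophobic	none
PHE	HD2	0.1	hydrophobic	none
PHE	HE1	0.1	hydrophobic	none
PHE	HE2	0.1	hydrophobic	none
PHE	HZ	0.1	hydrophobic	none
PRO	CB	0.5	hydrophobic	none
PRO	CD	0.1	hydrophobic	none
PRO	CG	0.5	hydrophobic	none
PRO	HD1	0.1	hydrophobic	none
PRO	HD2	0.1	hydrophobic	none
PRO	N	-0.6	polar-neutral	none
SER	CB	0.1	hydrophobic	none
SER	HB1	0.1	hydrophobic	none
SER	HB2	0.1	hydrophobic	none
SER	HG	-0.1	polar-neutral	none
SER	OG	-0.7	polar-neutral	both
THR	CB	0.1	hydrophobic	none
THR	CG2	0.5	hydrophobic	none
THR	HB	0.1	hydrophobic	none
THR	HG1	-0.1	polar-neutral	none
THR	OG1	-0.7	polar-neutral	both
TRP	CB	0.5	hydrophobic	none
TRP	CD1	0.1	hydrophobic	none
TRP	CD2	0.3	hydrophobic	none
TRP	CE2	0.1	hydrophobic	none
TRP	CE3	0.3	hydrophobic	none
TRP	CG	0.3	hydrophobic	none
TRP	CH2	0.3	hydrophobic	none
TRP	CZ2	0.3	hydrophobic	none
TRP	CZ3	0.3	hydrophobic	none
TRP	HD1	0.1	hydrophobic	none
TRP	HE1	-0.1	polar-neutral	none
TRP	HE3	0.1	hydrophobic	none
TRP	HH2	0.1	hydrophobic	none
TRP	HZ2	0.1	hydrophobic	none
TRP	HZ3	0.1	hydrophobic	none
TRP	NE1	-0.4	polar-neutral	donor
TYR	CB	0.5	hydrophobic	none
TYR	CD1	0.3	hydrophobic	none
TYR	CD2	0.3	hydrophobic	none
TYR	CE1	0.3	hydrophobic	none
TYR	CE2	0.3	hydrophobic	none
TYR	CG	0.3	hydrophobic	none
TYR	CZ	0.1	hydrophobic	none
TYR	HD1	0.1	hydrophobic	none
TYR	HD2	0.1	hydrophobic	none
TYR	HE1	0.1	hydrophobic	none
TYR	HE2	0.1	hydrophobic	none
TYR	HH	-0.1	polar-neutral	none
TYR	OH	-0.7	polar-neutral	both
VAL	CB	0.5	hydrophobic	none
VAL	CG1	0.5	hydrophobic	none
VAL	CG2	0.5	hydrophobic	none
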