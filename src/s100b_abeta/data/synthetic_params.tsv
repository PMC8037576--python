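# Synthetic united-atom-like parameter set for reduced peptide models
# (backbone N/CA/C/O plus one pseudo-sidechain sphere SC per residue).
# Rows with residue_name '*' are element fallbacks (radius only).
residue_name	atom_name	radius_nm	charge_e	sigma_nm	epsilon_kj
ALA	N	0.1625	-0.300	0.3100	0.650
ALA	CA	0.2000	0.300	0.3800	0.400
ALA	C	0.1900	0.450	0.3400	0.450
ALA	O	0.1500	-0.450	0.3000	0.850
ALA	SC	0.1700	0.000	0.3029	0.500
ARG	N	0.1625	-0.300	0.3100	0.650
ARG	CA	0.2000	0.300	0.3800	0.400
ARG	C	0.1900	0.450	0.3400	0.450
ARG	O	0.1500	-0.450	0.3000	0.850
ARG	SC	0.2600	1.000	0.4633	0.500
ASN	N	0.1625	-0.300	0.3100	0.650
ASN	CA	0.2000	0.300	0.3800	0.400
ASN	C	0.1900	0.450	0.3400	0.450
ASN	O	0.1500	-0.450	0.3000	0.850
ASN	SC	0.2200	0.000	0.3920	0.500
ASP	N	0.1625	-0.300	0.3100	0.650
ASP	CA	0.2000	0.300	0.3800	0.400
ASP	C	0.1900	0.450	0.3400	0.450
ASP	O	0.1500	-0.450	0.3000	0.850
ASP	SC	0.2200	-1.000	0.3920	0.500
CYS	N	0.1625	-0.300	0.3100	0.650
CYS	CA	0.2000	0.300	0.3800	0.400
CYS	C	0.1900	0.450	0.3400	0.450
CYS	O	0.1500	-0.450	0.3000	0.850
CYS	SC	0.2000	0.000	0.3564	0.500
GLN	N	0.1625	-0.300	0.3100	0.650
GLN	CA	0.2000	0.300	0.3800	0.400
GLN	C	0.1900	0.450	0.3400	0.450
GLN	O	0.1500	-0.450	0.3000	0.850
GLN	SC	0.2400	0.000	0.4276	0.500
GLU	N	0.1625	-0.300	0.3100	0.650
GLU	CA	0.2000	0.300	0.3800	0.400
GLU	C	0.1900	0.450	0.3400	0.450
GLU	O	0.1500	-0.450	0.3000	0.850
GLU	SC	0.2400	-1.000	0.4276	0.500
GLY	N	0.1625	-0.300	0.3100	0.650
GLY	CA	0.2000	0.300	0.3800	0.400
GLY	C	0.1900	0.450	0.3400	0.450
GLY	O	0.1500	-0.450	0.3000	0.850
GLY	SC	0.1200	0.000	0.2138	0.500
HIS	N	0.1625	-0.300	0.3100	0.650
HIS	CA	0.2000	0.300	0.3800	0.400
HIS	C	0.1900	0.450	0.3400	0.450
HIS	O	0.1500	-0.450	0.3000	0.850
HIS	SC	0.2400	0.000	0.4276	0.500
ILE	N	0.1625	-0.300	0.3100	0.650
ILE	CA	0.2000	0.300	0.3800	0.400
ILE	C	0.1900	0.450	0.3400	0.450
ILE	O	0.1500	-0.450	0.3000	0.850
ILE	SC	0.2400	0.000	0.4276	0.500
LEU	N	0.1625	-0.300	0.3100	0.650
LEU	CA	0.2000	0.300	0.3800	0.400
LEU	C	0.1900	0.450	0.3400	0.450
LEU	O	0.1500	-0.450	0.3000	0.850
LEU	SC	0.2400	0.000	0.4276	0.500
LYS	N	0.1625	-0.300	0.3100	0.650
LYS	CA	0.2000	0.300	0.3800	0.400
LYS	C	0.1900	0.450	0.3400	0.450
LYS	O	0.1500	-0.450	0.3000	0.850
LYS	SC	0.2500	1.000	0.4454	0.500
MET	N	0.1625	-0.300	0.3100	0.650
MET	CA	0.2000	0.300	0.3800	0.400
MET	C	0.1900	0.450	0.3400	0.450
MET	O	0.1500	-0.450	0.3000	0.850
MET	SC	0.2500	0.000	0.4454	0.500
PHE	N	0.1625	-0.300	0.3100	0.650
PHE	CA	0.2000	0.300	0.3800	0.400
PHE	C	0.1900	0.450	0.3400	0.450
PHE	O	0.1500	-0.450	0.3000	0.850
PHE	SC	0.2600	0.000	0.4633	0.500
PRO	N	0.1625	-0.300	0.3100	0.650
PRO	CA	0.2000	0.300	0.3800	0.400
PRO	C	0.1900	0.450	0.3400	0.450
PRO	O	0.1500	-0.450	0.3000	0.850
PRO	SC	0.2100	0.000	0.3742	0.500
SER	N	0.1625	-0.300	0.3100	0.650
SER	CA	0.2000	0.300	0.3800	0.400
SER	C	0.1900	0.450	0.3400	0.450
SER	O	0.1500	-0.450	0.3000	0.850
SER	SC	0.1800	0.000	0.3207	0.500
THR	N	0.1625	-0.300	0.3100	0.650
THR	CA	0.2000	0.300	0.3800	0.400
THR	C	0.1900	0.450	0.3400	0.450
THR	O	0.1500	-0.450	0.3000	0.850
THR	SC	0.2100	0.000	0.3742	0.500
TRP	N	0.1625	-0.300	0.3100	0.650
TRP	CA	0.2000	0.300	0.3800	0.400
TRP	C	0.1900	0.450	0.3400	0.450
TRP	O	0.1500	-0.450	0.3000	0.850
TRP	SC	0.2900	0.000	0.5167	0.500
TYR	N	0.1625	-0.300	0.3100	0.650
TYR	CA	0.2000	0.300	0.3800	0.400
TYR	C	0.1900	0.450	0.3400	0.450
TYR	O	0.1500	-0.450	0.3000	0.850
TYR	SC	0.2700	0.000	0.4811	0.500
VAL	N	0.1625	-0.300	0.3100	0.650
VAL	CA	0.2000	0.300	0.3800	0.400
VAL	C	0.1900	0.450	0.3400	0.450
VAL	O	0.1500	-0.450	0.3000	0.850
VAL	SC	0.2200	0.000	0.3920	0.500
*	C	0.1850	0.000	0.0000	0.000
*	N	0.1625	0.000	0.0000	0.000
*	O	0.1500	0.000	0.0000	0.000
*	S	0.1800	0.000	0.0000	0.000
*	H	0.1100	0.000	0.0000	0.000
*	P	0.1900	0.000	0.0000	0.000
*	Ca	0.2400	0.000	0.0000	0.000
*	Zn	0.2100	0.000	0.0000	0.000
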