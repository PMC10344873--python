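# residue_type	chi_angles (comma-separated degrees; blank = no chi)
ALA	
ARG	-60,180,180,180
ARG	180,180,180,180
ARG	60,180,180,180
ASN	-60,0
ASN	180,0
ASN	60,0
ASP	-60,0
ASP	180,0
ASP	60,0
CYS	-60
CYS	60
CYS	180
GLN	-60,180,0
GLN	180,180,0
GLN	60,180,0
GLU	-60,180,0
GLU	180,180,0
GLU	60,180,0
GLY	
HIS	-60,90
HIS	180,90
HIS	60,90
ILE	-60,180
ILE	180,180
ILE	60,180
LEU	-60,180
LEU	180,60
LEU	60,180
LYS	-60,180,180,180
LYS	180,180,180,180
LYS	60,180,180,180
MET	-60,180,180
MET	180,180,180
MET	60,180,180
PHE	-60,90
PHE	180,90
PHE	60,90
PRO	30,-35
SER	-60
SER	60
SER	180
THR	-60
THR	60
THR	180
TRP	-60,90
TRP	180,90
TRP	60,90
TYR	-60,90
TYR	180,90
TYR	60,90
VAL	-60
VAL	60
VAL	180
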