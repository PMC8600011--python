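residue,atom,classes
ALA,C,neutral
ALA,CA,hydrophobic
ALA,CB,hydrophobic
ALA,N,donor
ALA,O,acceptor
ALA,OXT,acceptor;negative
ARG,C,neutral
ARG,CA,hydrophobic
ARG,CB,hydrophobic
ARG,CD,hydrophobic
ARG,CG,hydrophobic
ARG,CZ,positive
ARG,N,donor
ARG,NE,donor;positive
ARG,NH1,donor;positive
ARG,NH2,donor;positive
ARG,O,acceptor
ARG,OXT,acceptor;negative
ASN,C,neutral
ASN,CA,hydrophobic
ASN,CB,hydrophobic
ASN,CG,neutral
ASN,N,donor
ASN,ND2,donor
ASN,O,acceptor
ASN,OD1,acceptor
ASN,OXT,acceptor;negative
ASP,C,neutral
ASP,CA,hydrophobic
ASP,CB,hydrophobic
ASP,CG,neutral
ASP,N,donor
ASP,O,acceptor
ASP,OD1,acceptor;negative
ASP,OD2,acceptor;negative
ASP,OXT,acceptor;negative
CYS,C,neutral
CYS,CA,hydrophobic
CYS,CB,hydrophobic
CYS,N,donor
CYS,O,acceptor
CYS,OXT,acceptor;negative
CYS,SG,acceptor;donor
GLN,C,neutral
GLN,CA,hydrophobic
GLN,CB,hydrophobic
GLN,CD,neutral
GLN,CG,hydrophobic
GLN,N,donor
GLN,NE2,donor
GLN,O,acceptor
GLN,OE1,acceptor
GLN,OXT,acceptor;negative
GLU,C,neutral
GLU,CA,hydrophobic
GLU,CB,hydrophobic
GLU,CD,neutral
GLU,CG,hydrophobic
GLU,N,donor
GLU,O,acceptor
GLU,OE1,acceptor;negative
GLU,OE2,acceptor;negative
GLU,OXT,acceptor;negative
GLY,C,neutral
GLY,CA,hydrophobic
GLY,N,donor
GLY,O,acceptor
GLY,OXT,acceptor;negative
HIS,C,neutral
HIS,CA,hydrophobic
HIS,CB,hydrophobic
HIS,CD2,aromatic
HIS,CE1,aromatic
HIS,CG,aromatic
HIS,N,donor
HIS,ND1,acceptor;aromatic;donor;positive
HIS,NE2,acceptor;aromatic;donor;positive
HIS,O,acceptor
HIS,OXT,acceptor;negative
ILE,C,neutral
ILE,CA,hydrophobic
ILE,CB,hydrophobic
ILE,CD1,hydrophobic
ILE,CG1,hydrophobic
ILE,CG2,hydrophobic
ILE,N,donor
ILE,O,acceptor
ILE,OXT,acceptor;negative
LEU,C,neutral
LEU,CA,hydrophobic
LEU,CB,hydrophobic
LEU,CD1,hydrophobic
LEU,CD2,hydrophobic
LEU,CG,hydrophobic
LEU,N,donor
LEU,O,acceptor
LEU,OXT,acceptor;negative
LYS,C,neutral
LYS,CA,hydrophobic
LYS,CB,hydrophobic
LYS,CD,hydrophobic
LYS,CE,hydrophobic
LYS,CG,hydrophobic
LYS,N,donor
LYS,NZ,donor;positive
LYS,O,acceptor
LYS,OXT,acceptor;negative
MET,C,neutral
MET,CA,hydrophobic
MET,CB,hydrophobic
MET,CE,hydrophobic
MET,CG,hydrophobic
MET,N,donor
MET,O,acceptor
MET,OXT,acceptor;negative
MET,SD,acceptor;hydrophobic
PHE,C,neutral
PHE,CA,hydrophobic
PHE,CB,hydrophobic
PHE,CD1,aromatic
PHE,CD2,aromatic
PHE,CE1,aromatic
PHE,CE2,aromatic
PHE,CG,aromatic
PHE,CZ,aromatic
PHE,N,donor
PHE,O,acceptor
PHE,OXT,acceptor;negative
PRO,C,neutral
PRO,CA,hydrophobic
PRO,CB,hydrophobic
PRO,CD,hydrophobic
PRO,CG,hydrophobic
PRO,N,neutral
PRO,O,acceptor
PRO,OXT,acceptor;negative
SER,C,neutral
SER,CA,hydrophobic
SER,CB,hydrophobic
SER,N,donor
SER,O,acceptor
SER,OG,acceptor;donor
SER,OXT,acceptor;negative
THR,C,neutral
THR,CA,hydrophobic
THR,CB,hydrophobic
THR,CG2,hydrophobic
THR,N,donor
THR,O,acceptor
THR,OG1,acceptor;donor
THR,OXT,acceptor;negative
TRP,C,neutral
TRP,CA,hydrophobic
TRP,CB,hydrophobic
TRP,CD1,aromatic
TRP,CD2,aromatic
TRP,CE2,aromatic
TRP,CE3,aromatic
TRP,CG,aromatic
TRP,CH2,aromatic
TRP,CZ2,aromatic
TRP,CZ3,aromatic
TRP,N,donor
TRP,NE1,aromatic
TRP,O,acceptor
TRP,OXT,acceptor;negative
TYR,C,neutral
TYR,CA,hydrophobic
TYR,CB,hydrophobic
TYR,CD1,aromatic
TYR,CD2,aromatic
TYR,CE1,aromatic
TYR,CE2,aromatic
TYR,CG,aromatic
TYR,CZ,aromatic
TYR,N,donor
TYR,O,acceptor
TYR,OH,acceptor;donor
TYR,OXT,acceptor;negative
VAL,C,neutral
VAL,CA,hydrophobic
VAL,CB,hydrophobic
VAL,CG1,hydrophobic
VAL,CG2,hydrophobic
VAL,N,donor
VAL,O,acceptor
VAL,OXT,acceptor;negative
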