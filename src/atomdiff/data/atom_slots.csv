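residue,atom,atom37_index,atom73_slot
ALA,N,0,0
ALA,CA,1,1
ALA,C,2,2
ALA,O,4,4
ALA,CB,3,3
ARG,N,0,0
ARG,CA,1,1
ARG,C,2,2
ARG,O,4,4
ARG,CB,3,3
ARG,CG,5,5
ARG,CD,11,6
ARG,NE,23,7
ARG,NH1,29,8
ARG,NH2,30,9
ARG,CZ,32,10
ASN,N,0,0
ASN,CA,1,1
ASN,C,2,2
ASN,O,4,4
ASN,CB,3,3
ASN,CG,5,11
ASN,ND2,15,12
ASN,OD1,16,13
ASP,N,0,0
ASP,CA,1,1
ASP,C,2,2
ASP,O,4,4
ASP,CB,3,3
ASP,CG,5,14
ASP,OD1,16,15
ASP,OD2,17,16
CYS,N,0,0
CYS,CA,1,1
CYS,C,2,2
CYS,O,4,4
CYS,CB,3,3
CYS,SG,10,17
GLN,N,0,0
GLN,CA,1,1
GLN,C,2,2
GLN,O,4,4
GLN,CB,3,3
GLN,CG,5,18
GLN,CD,11,19
GLN,NE2,25,20
GLN,OE1,26,21
GLU,N,0,0
GLU,CA,1,1
GLU,C,2,2
GLU,O,4,4
GLU,CB,3,3
GLU,CG,5,22
GLU,CD,11,23
GLU,OE1,26,24
GLU,OE2,27,25
GLY,N,0,0
GLY,CA,1,1
GLY,C,2,2
GLY,O,4,4
HIS,N,0,0
HIS,CA,1,1
HIS,C,2,2
HIS,O,4,4
HIS,CB,3,3
HIS,CG,5,26
HIS,CD2,13,27
HIS,ND1,14,28
HIS,CE1,20,29
HIS,NE2,25,30
ILE,N,0,0
ILE,CA,1,1
ILE,C,2,2
ILE,O,4,4
ILE,CB,3,3
ILE,CG1,6,31
ILE,CG2,7,32
ILE,CD1,12,33
LEU,N,0,0
LEU,CA,1,1
LEU,C,2,2
LEU,O,4,4
LEU,CB,3,3
LEU,CG,5,34
LEU,CD1,12,35
LEU,CD2,13,36
LYS,N,0,0
LYS,CA,1,1
LYS,C,2,2
LYS,O,4,4
LYS,CB,3,3
LYS,CG,5,37
LYS,CD,11,38
LYS,CE,19,39
LYS,NZ,35,40
MET,N,0,0
MET,CA,1,1
MET,C,2,2
MET,O,4,4
MET,CB,3,3
MET,CG,5,41
MET,SD,18,42
MET,CE,19,43
PHE,N,0,0
PHE,CA,1,1
PHE,C,2,2
PHE,O,4,4
PHE,CB,3,3
PHE,CG,5,44
PHE,CD1,12,45
PHE,CD2,13,46
PHE,CE1,20,47
PHE,CE2,21,48
PHE,CZ,32,49
PRO,N,0,0
PRO,CA,1,1
PRO,C,2,2
PRO,O,4,4
PRO,CB,3,3
PRO,CG,5,50
PRO,CD,11,51
SER,N,0,0
SER,CA,1,1
SER,C,2,2
SER,O,4,4
SER,CB,3,3
SER,OG,8,52
THR,N,0,0
THR,CA,1,1
THR,C,2,2
THR,O,4,4
THR,CB,3,3
THR,CG2,7,53
THR,OG1,9,54
TRP,N,0,0
TRP,CA,1,1
TRP,C,2,2
TRP,O,4,4
TRP,CB,3,3
TRP,CG,5,55
TRP,CD1,12,56
TRP,CD2,13,57
TRP,CE2,21,58
TRP,CE3,22,59
TRP,NE1,24,60
TRP,CH2,28,61
TRP,CZ2,33,62
TRP,CZ3,34,63
TYR,N,0,0
TYR,CA,1,1
TYR,C,2,2
TYR,O,4,4
TYR,CB,3,3
TYR,CG,5,64
TYR,CD1,12,65
TYR,CD2,13,66
TYR,CE1,20,67
TYR,CE2,21,68
TYR,OH,31,69
TYR,CZ,32,70
VAL,N,0,0
VAL,CA,1,1
VAL,C,2,2
VAL,O,4,4
VAL,CB,3,3
VAL,CG1,6,71
VAL,CG2,7,72
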