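residue,atom,class
ASP,OD1,OD1|OD2
ASP,OD2,OD1|OD2
GLU,OE1,OE1|OE2
GLU,OE2,OE1|OE2
ARG,NH1,NH1|NH2
ARG,NH2,NH1|NH2
PHE,CD1,CD1|CD2
PHE,CD2,CD1|CD2
PHE,CE1,CE1|CE2
PHE,CE2,CE1|CE2
TYR,CD1,CD1|CD2
TYR,CD2,CD1|CD2
TYR,CE1,CE1|CE2
TYR,CE2,CE1|CE2
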