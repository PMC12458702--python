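role,residue,atom
basic,LYS,NZ
basic,ARG,NH1
basic,ARG,NH2
basic,ARG,NE
basic,HIS,ND1
basic,HIS,NE2
acidic,ASP,OD1
acidic,ASP,OD2
acidic,GLU,OE1
acidic,GLU,OE2
acidic,*,OXT
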