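role,residue,atom
donor,*,N
donor,SER,OG
donor,THR,OG1
donor,TYR,OH
donor,CYS,SG
donor,LYS,NZ
donor,ARG,NE
donor,ARG,NH1
donor,ARG,NH2
donor,HIS,ND1
donor,HIS,NE2
donor,ASN,ND2
donor,GLN,NE2
donor,TRP,NE1
acceptor,*,O
acceptor,*,OXT
acceptor,ASP,OD1
acceptor,ASP,OD2
acceptor,GLU,OE1
acceptor,GLU,OE2
acceptor,ASN,OD1
acceptor,GLN,OE1
acceptor,SER,OG
acceptor,THR,OG1
acceptor,TYR,OH
acceptor,HIS,ND1
acceptor,HIS,NE2
acceptor,MET,SD
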