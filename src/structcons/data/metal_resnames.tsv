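# Heteroatom residue names treated as catalytic/structural metal ions.
resname
ZN
MG
MN
FE
FE2
FES
CU
CU1
NI
CO
MO
W
CA
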