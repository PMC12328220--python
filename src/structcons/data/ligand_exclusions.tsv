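# Heteroatom residue names ignored when detecting contact-site (CSb) binding
# residues: waters, cryoprotectants, buffers and common crystallisation additives.
# Monoatomic alkali/halide ions are excluded; transition metals and Mg are kept
# (metal sites are biologically meaningful) and additionally flagged as metals.
resname	kind
HOH	water
WAT	water
DOD	water
SO4	buffer
PO4	buffer
GOL	cryo
EDO	cryo
PEG	cryo
PG4	cryo
PGE	cryo
1PE	cryo
MPD	cryo
DMS	solvent
ACT	buffer
ACY	buffer
FMT	buffer
TRS	buffer
EPE	buffer
MES	buffer
CIT	buffer
TAR	buffer
MLI	buffer
NO3	buffer
BME	reducing
MRD	cryo
NA	ion
K	ion
CL	ion
BR	ion
IOD	ion
CS	ion
NH4	ion
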