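# Default physicochemical grouping of the 20 canonical amino acids.
# Glycine, proline and cysteine form their own singleton classes.
aa	aa_class
A	aliphatic
V	aliphatic
L	aliphatic
I	aliphatic
M	aliphatic
F	aromatic
W	aromatic
Y	aromatic
S	polar
T	polar
N	polar
Q	polar
D	acidic
E	acidic
K	basic
R	basic
H	basic
G	glycine
P	proline
C	cysteine
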