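# Per-residue biosynthetic cost metrics.
# atp: Akashi/Gojobori-style ATP-equivalent synthesis cost (high-energy phosphate bonds).
# opportunity: Wagner-style respiratory opportunity cost (~ATP equivalents).
# mw: residue molecular weight (Da), a size proxy.
# Metrics are median-normalised at load time for cross-metric comparison.
aa	atp	opportunity	mw
A	11.7	14.5	71.08
R	27.3	20.5	156.19
N	14.7	18.5	114.10
D	12.7	15.5	115.09
C	24.7	26.5	103.14
E	15.3	9.5	129.12
Q	16.3	10.5	128.13
G	11.7	14.5	57.05
H	38.3	29.0	137.14
I	32.3	38.0	113.16
L	27.3	37.0	113.16
K	30.3	36.0	128.17
M	34.3	36.5	131.19
F	52.0	61.0	147.18
P	20.3	14.5	97.12
S	11.7	14.5	87.08
T	18.7	21.5	101.10
W	74.3	75.5	186.21
Y	50.0	59.0	163.18
V	23.3	29.0	99.13
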