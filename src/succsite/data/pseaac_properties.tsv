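# Raw physicochemical property values used by the Type-1 pseudo amino acid
# composition encoder. Columns:
#   aa              one-letter code (20 standard amino acids)
#   hydrophobicity  Tanford/Chou consensus hydrophobicity scale as used by
#                   Chou's original PseAAC web server
#   hydrophilicity  Hopp & Woods (1981) hydrophilicity scale
#   side_chain_mass side-chain mass in Daltons (integer convention of the
#                   PseAAC literature; glycine side chain = 1 H)
# Each column is standardized to zero mean / unit SD over the 20 amino acids
# at load time; only the standardized values enter the encoder. Swap this
# file (or load another with AAIndexTable.from_tsv) to use different scales.
aa	hydrophobicity	hydrophilicity	side_chain_mass
A	0.62	-0.5	15
R	-2.53	3.0	101
N	-0.78	0.2	58
D	-0.90	3.0	59
C	0.29	-1.0	47
Q	-0.85	0.2	72
E	-0.74	3.0	73
G	0.48	0.0	1
H	-0.40	-0.5	82
I	1.38	-1.8	57
L	1.06	-1.8	57
K	-1.50	3.0	73
M	0.64	-1.3	75
F	1.19	-2.5	91
P	0.12	0.0	42
S	-0.18	0.3	31
T	-0.05	-0.4	45
W	0.81	-3.4	130
Y	0.26	-2.3	107
V	1.08	-1.5	43
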