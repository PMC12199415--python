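residue	hydrophilicity	hydrophobicity	tiny	acidity	positively_charged	negatively_charged	polarity	aromaticity	sulfur	aliphatic
A	0	1	1	0	0	0	0	0	0	1
C	0	1	1	0	0	0	1	0	1	0
D	1	0	0	1	0	1	1	0	0	0
E	1	0	0	1	0	1	1	0	0	0
F	0	1	0	0	0	0	0	1	0	0
G	0	0	1	0	0	0	0	0	0	1
H	1	0	0	0	1	0	1	1	0	0
I	0	1	0	0	0	0	0	0	0	1
K	1	0	0	0	1	0	1	0	0	0
L	0	1	0	0	0	0	0	0	0	1
M	0	1	0	0	0	0	0	0	1	0
N	1	0	0	0	0	0	1	0	0	0
P	0	0	0	0	0	0	0	0	0	1
Q	1	0	0	0	0	0	1	0	0	0
R	1	0	0	0	1	0	1	0	0	0
S	1	0	1	0	0	0	1	0	0	0
T	1	0	1	0	0	0	1	0	0	0
V	0	1	0	0	0	0	0	0	0	1
W	0	1	0	0	0	0	0	1	0	0
Y	0	0	0	0	0	0	1	1	0	0
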