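A	0.079
C	0.017
D	0.056
E	0.063
F	0.045
G	0.072
H	0.027
I	0.056
K	0.054
L	0.080
M	0.021
N	0.045
P	0.046
Q	0.037
R	0.053
S	0.063
T	0.057
V	0.066
W	0.018
Y	0.045
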