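# RC conformation probabilities, beta-D-glucopyranose (MD-free ED analysis)
# columns: label	rotamer	probability
A	GG	0.10
B	GG	0.10
C	GG	0.11
D	GG	0.10
E	GT	0.13
F	GT	0.14
G	GT	0.13
H	GG	0.07
I	GG	0.04
L	GG	0.04
M	GG	0.04
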