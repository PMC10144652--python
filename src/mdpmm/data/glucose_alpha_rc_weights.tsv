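# RC conformation probabilities, alpha-D-glucopyranose (MD-free ED analysis)
# columns: label	rotamer	probability
A	GT	0.10
B	GT	0.10
C	GT	0.09
D	GT	0.13
E	GG	0.10
F	GG	0.09
G	GG	0.09
H	GG	0.08
I	GG	0.10
L	GG	0.10
M	GG	0.11
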