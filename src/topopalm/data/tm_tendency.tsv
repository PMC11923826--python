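residue	value
A	0.38
R	-2.57
N	-1.62
D	-3.27
C	-0.30
Q	-1.84
E	-2.90
G	-0.19
H	-1.44
I	1.97
L	1.82
K	-3.46
M	1.40
F	1.98
P	-1.44
S	-0.53
T	-0.32
W	1.53
Y	0.49
V	1.46
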