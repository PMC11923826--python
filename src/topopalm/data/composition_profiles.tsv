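residue	transmembrane	soluble	signal
A	0.120	0.070	0.110
R	0.005	0.060	0.030
N	0.010	0.045	0.020
D	0.005	0.055	0.010
C	0.020	0.030	0.020
Q	0.010	0.045	0.020
E	0.005	0.065	0.010
G	0.060	0.065	0.060
H	0.010	0.025	0.015
I	0.140	0.040	0.080
L	0.190	0.085	0.200
K	0.005	0.060	0.025
M	0.035	0.020	0.030
F	0.110	0.035	0.070
P	0.020	0.050	0.030
S	0.055	0.075	0.090
T	0.050	0.055	0.060
W	0.030	0.012	0.020
Y	0.035	0.028	0.030
V	0.085	0.080	0.070
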