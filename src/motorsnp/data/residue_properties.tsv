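aa	charge	polarity	max_asa	helix_penalty
A	0	nonpolar	129	0.00
R	1	charged	274	0.21
N	0	polar	195	0.65
D	-1	charged	193	0.69
C	0	nonpolar	167	0.68
E	-1	charged	223	0.40
Q	0	polar	225	0.39
G	0	nonpolar	104	1.00
H	0	polar	224	0.61
I	0	nonpolar	197	0.41
L	0	nonpolar	201	0.21
K	1	charged	236	0.26
M	0	nonpolar	224	0.24
F	0	nonpolar	240	0.54
P	0	nonpolar	159	3.16
S	0	polar	155	0.50
T	0	polar	172	0.66
W	0	nonpolar	285	0.49
Y	0	polar	263	0.53
V	0	nonpolar	174	0.61
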