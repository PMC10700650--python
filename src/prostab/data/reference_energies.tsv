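aa	energy
A	0.00
L	0.21
R	0.21
M	0.24
K	0.26
Q	0.39
E	0.40
I	0.41
W	0.49
S	0.50
Y	0.53
F	0.54
H	0.61
V	0.61
N	0.65
T	0.66
C	0.68
D	0.69
G	1.00
P	3.16
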