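element	monoisotopic_mass
H	1.0078250
C	12.0000000
N	14.0030740
O	15.9949146
F	18.9984032
Na	22.9897693
P	30.9737616
S	31.9720710
Cl	34.9688527
K	38.9637067
Br	78.9183371
I	126.9044730
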