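# Per-residue property scales (editable fixture).
# kyte_doolittle: hydropathy (Kyte & Doolittle 1982, J Mol Biol 157:105).
# kanehisa_tsong: relative beta-sheet propensity (Kanehisa & Tsong 1980,
#   Biopolymers 19:1617; AAindex KANM800102), transcribed for convenience —
#   edit here to swap in another beta-propensity scale.
aa	kyte_doolittle	kanehisa_tsong
A	1.8	0.90
R	-4.5	0.99
N	-3.5	0.76
D	-3.5	0.72
C	2.5	0.91
Q	-3.5	1.13
E	-3.5	0.66
G	-0.4	0.92
H	-3.2	1.00
I	4.5	1.54
L	3.8	1.26
K	-3.9	0.78
M	1.9	1.09
F	2.8	1.23
P	-1.6	0.64
S	-0.8	0.82
T	-0.7	1.17
W	-0.9	1.07
Y	-1.3	1.23
V	4.2	1.41
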