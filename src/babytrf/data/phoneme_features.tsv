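# Phoneme -> articulatory feature lookup (ARPAbet-like symbols).
# Reconstructed from the standard articulatory-phonetics convention
# (voicing, manner, place) for a British-English inventory; editable.
# Columns: 1 marks that the phoneme carries the feature.
phoneme	voiced consonant	unvoiced consonant	plosive	fricative	nasal	strident	labial	coronal	dorsal	anterior	front	back	high	low
P	0	1	1	0	0	0	1	0	0	1	0	0	0	0
B	1	0	1	0	0	0	1	0	0	1	0	0	0	0
T	0	1	1	0	0	0	0	1	0	1	0	0	0	0
D	1	0	1	0	0	0	0	1	0	1	0	0	0	0
K	0	1	1	0	0	0	0	0	1	0	0	0	0	0
G	1	0	1	0	0	0	0	0	1	0	0	0	0	0
CH	0	1	1	1	0	1	0	1	0	0	0	0	0	0
JH	1	0	1	1	0	1	0	1	0	0	0	0	0	0
F	0	1	0	1	0	1	1	0	0	1	0	0	0	0
V	1	0	0	1	0	1	1	0	0	1	0	0	0	0
TH	0	1	0	1	0	0	0	1	0	1	0	0	0	0
DH	1	0	0	1	0	0	0	1	0	1	0	0	0	0
S	0	1	0	1	0	1	0	1	0	1	0	0	0	0
Z	1	0	0	1	0	1	0	1	0	1	0	0	0	0
SH	0	1	0	1	0	1	0	1	0	0	0	0	0	0
ZH	1	0	0	1	0	1	0	1	0	0	0	0	0	0
HH	0	1	0	1	0	0	0	0	0	0	0	0	0	0
M	1	0	0	0	1	0	1	0	0	1	0	0	0	0
N	1	0	0	0	1	0	0	1	0	1	0	0	0	0
NG	1	0	0	0	1	0	0	0	1	0	0	0	0	0
L	1	0	0	0	0	0	0	1	0	1	0	0	0	0
R	1	0	0	0	0	0	0	1	0	0	0	0	0	0
W	1	0	0	0	0	0	1	0	1	0	0	1	1	0
Y	1	0	0	0	0	0	0	0	1	0	1	0	1	0
IY	0	0	0	0	0	0	0	0	0	0	1	0	1	0
IH	0	0	0	0	0	0	0	0	0	0	1	0	1	0
EH	0	0	0	0	0	0	0	0	0	0	1	0	0	0
AE	0	0	0	0	0	0	0	0	0	0	1	0	0	1
AH	0	0	0	0	0	0	0	0	0	0	0	1	0	1
AA	0	0	0	0	0	0	0	0	0	0	0	1	0	1
AO	0	0	0	0	0	0	0	0	0	0	0	1	0	0
UH	0	0	0	0	0	0	0	0	0	0	0	1	1	0
UW	0	0	0	0	0	0	0	0	0	0	0	1	1	0
ER	0	0	0	0	0	0	0	0	0	0	0	1	0	0
AX	0	0	0	0	0	0	0	0	0	0	0	1	0	0
EY	0	0	0	0	0	0	0	0	0	0	1	0	0	0
AY	0	0	0	0	0	0	0	0	0	0	1	0	0	1
OY	0	0	0	0	0	0	0	0	0	0	0	1	0	0
OW	0	0	0	0	0	0	0	0	0	0	0	1	0	0
AW	0	0	0	0	0	0	0	0	0	0	0	1	0	1
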