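# ancsite packaged physicochemical recoding scheme
# residue -> category (snake_case identifier)
# C, H, P are deliberately absent: they recode to singleton categories named
# by their own letter, so no unsupported similarity is asserted.
residue	category
E	acidic
D	acidic
I	aliphatic
L	aliphatic
M	aliphatic
V	aliphatic
Q	amine
N	amine
W	aromatic
Y	aromatic
F	aromatic
K	basic
R	basic
S	small_hydroxyl
T	small_hydroxyl
A	tiny
G	tiny
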