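# Kyte-Doolittle hydropathy scale (J Mol Biol 157:105-132, 1982) with
# hydrophobicity class labels, v1. Class labels for residues appearing in the
# published FBP1 mutation panel follow the panel's usage (G and P counted as
# hydrophobic-aliphatic); the remainder follow standard biochemistry
# conventions (C/M grouped with the aliphatics, Y with the aromatics).
aa	hydropathy	class_label
A	1.8	hydrophobic-aliphatic
C	2.5	hydrophobic-aliphatic
D	-3.5	hydrophilic-acidic
E	-3.5	hydrophilic-acidic
F	2.8	hydrophobic-aromatic
G	-0.4	hydrophobic-aliphatic
H	-3.2	hydrophilic-basic
I	4.5	hydrophobic-aliphatic
K	-3.9	hydrophilic-basic
L	3.8	hydrophobic-aliphatic
M	1.9	hydrophobic-aliphatic
N	-3.5	hydrophilic-neutral
P	-1.6	hydrophobic-aliphatic
Q	-3.5	hydrophilic-neutral
R	-4.5	hydrophilic-basic
S	-0.8	hydrophilic-neutral
T	-0.7	hydrophilic-neutral
V	4.2	hydrophobic-aliphatic
W	-0.9	hydrophobic-aromatic
Y	-1.3	hydrophobic-aromatic
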