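# Synthetic, simplified mtDNA haplogroup table (NOT a Phylotree import).
# Columns: name, parent, space-separated diagnostic variant tokens acquired
# on the branch into the node.  Topology and diagnostic sets are a curated
# stand-in covering the eight case haplogroups and their ancestors; anchor
# positions use control-region sites with well-known reference bases.
name	parent	diagnostics
root
R	root	73G
N	root	16223T
HV	R	263G
U	R	16224C
J	R	16069T 16126C
H	HV	152C
HV1b	HV	16067T
V	HV	16298C
H3	H	16093C
H3p	H3	16189C 16304C
HV1b2	HV1b	16319A 195C
V7a	V	16153A 204C
K	U	16311C
K1a1b1a	K	114T 16234T 16092C
K2a2a1	K	146C 16048A 16111T
J1c14	J	185A 228A 16145A
I	N	199C 250C
X	N	200G 16278T
I1c1a	I	16129A 203A 16172C
X2b7	X	225A 16183C 16256T
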