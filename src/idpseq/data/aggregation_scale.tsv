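# Built-in per-residue aggregation-propensity scale: the mean of (i) Kyte-
# Doolittle hydropathy rescaled to [0,1] over its -4.5..4.5 range and (ii)
# Chou-Fasman beta-sheet propensity rescaled to [0,1] over its 0.37..1.70
# range.  Hydrophobic beta-prone segments score high, as expected of
# aggregation-nucleating stretches.
# Defaults: window=7; threshold=0.692, calibrated once so that
# ~10% of residues of random globular-composition sequences fall inside an
# aggregation-prone window.
residue	value
A	0.5229
C	0.6972
D	0.1195
E	0.0556
F	0.7853
G	0.3706
H	0.2602
I	0.9624
K	0.1724
L	0.8107
M	0.6112
N	0.2510
P	0.2288
Q	0.3300
R	0.2105
S	0.3484
T	0.5194
V	0.9833
W	0.5759
Y	0.5913
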