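# Per-residue secondary-structure propensities (Chou-Fasman conformational
# parameters: P_alpha, P_beta, P_turn used as the coil channel).  Consumed by
# the windowed-propensity predictor; per-position label = argmax of the
# window-averaged channels with ties resolved C > H > E.
residue	p_helix	p_sheet	p_coil
A	1.42	0.83	0.66
C	0.70	1.19	1.19
D	1.01	0.54	1.46
E	1.51	0.37	0.74
F	1.13	1.38	0.60
G	0.57	0.75	1.56
H	1.00	0.87	0.95
I	1.08	1.60	0.47
K	1.14	0.74	1.01
L	1.21	1.30	0.59
M	1.45	1.05	0.60
N	0.67	0.89	1.56
P	0.57	0.55	1.52
Q	1.11	1.10	0.98
R	0.98	0.93	0.95
S	0.77	0.75	1.43
T	0.83	1.19	0.96
V	1.06	1.70	0.50
W	1.08	1.37	0.96
Y	0.69	1.47	1.14
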