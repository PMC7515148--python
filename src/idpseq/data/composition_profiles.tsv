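# Default residue-frequency profiles for the synthetic sequence generator.
# globular: database background frequencies (hydrophobics well represented).
# polar_tract: background with G, P, S, Q mass doubled then renormalized,
#   emulating polar low-complexity disordered regions.
# charged: background with E, K, A mass doubled then renormalized, emulating
#   polyampholyte-like disordered regions.
residue	globular	polar_tract	charged
A	0.082583	0.067534	0.136657
C	0.013814	0.011297	0.011430
D	0.054555	0.044614	0.045138
E	0.067568	0.055255	0.111811
F	0.038639	0.031598	0.031970
G	0.070771	0.115750	0.058556
H	0.022723	0.018582	0.018801
I	0.059660	0.048788	0.049362
K	0.058458	0.047806	0.096737
L	0.096697	0.079077	0.080007
M	0.024224	0.019810	0.020043
N	0.040641	0.033235	0.033626
P	0.047047	0.076948	0.038927
Q	0.039339	0.064342	0.032549
R	0.055355	0.045269	0.045801
S	0.065666	0.107400	0.054332
T	0.053453	0.043713	0.044227
V	0.068769	0.056238	0.056899
W	0.010811	0.008841	0.008945
Y	0.029229	0.023903	0.024184
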