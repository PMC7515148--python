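# Reduction of 8-state secondary-structure labels to the 3-state alphabet:
# helices (G, H, I) -> H; extended/bridge (E, B) -> E; everything else
# (T, S, C, '-') -> C.  Applied when reading external predictor tracks.
label8	label3
G	H
H	H
I	H
E	E
B	E
T	C
S	C
C	C
-	C
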