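# IPC_protein pKa set, Kozlowski (2016) Biology Direct 11:55.
# Nine ionizable groups: N-/C-terminus plus the side chains of D, E, C, Y
# (acidic) and H, K, R (basic).
group	pka	kind
nterm	9.094	basic
cterm	2.869	acidic
D	3.872	acidic
E	4.412	acidic
C	7.555	acidic
Y	10.85	acidic
H	5.637	basic
K	9.052	basic
R	11.84	basic
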