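# Synthetic PLS motif table for an IPI1-like DYW-class PPR protein:
# 13 PLS repeats followed by E/E+/DYW regions (the terminal regions carry no
# code residues that contribute PWM columns and are dropped by the parser).
# The last PLS motif has no following motif, so aa1p is a gap.
index	class	aa6	aa1p
1	P	T	N
2	L	N	D
3	S	N	D
4	P	T	N
5	L	T	D
6	S	T	N
7	P	S	N
8	L	N	D
9	S	N	S
10	P	T	N
11	L	N	D
12	S	N	S
13	P	T	-
14	E	S	S
15	E+	A	A
16	DYW	D	W
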