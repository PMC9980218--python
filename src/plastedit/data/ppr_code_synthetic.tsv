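# Synthetic PPR code table: nucleotide preference per (aa6, aa1') residue pair.
# Encodes the canonical qualitative PLS recognition code (T/D->G, T/N->A,
# S/N->A, S/D->G, N/D->U, N/S->C, N/N->pyrimidine) with synthetic weights;
# the published quantitative weighting scheme is not redistributed here.
# Pairs absent from this table fall back to a uniform column.
aa6	aa1p	pA	pC	pG	pU
T	D	0.08	0.04	0.84	0.04
T	N	0.76	0.06	0.10	0.08
S	N	0.68	0.12	0.10	0.10
S	D	0.14	0.06	0.74	0.06
N	D	0.06	0.14	0.04	0.76
N	S	0.12	0.60	0.06	0.22
N	N	0.14	0.42	0.04	0.40
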