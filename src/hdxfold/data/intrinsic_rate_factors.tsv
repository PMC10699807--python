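# Side-chain inductive/steric factors for backbone amide H->D exchange in D2O,
# log10 multiplicative corrections relative to poly-DL-alanine.
# Transcribed from the standard reference-parameter compilation for intrinsic
# amide exchange rates (Bai, Milne, Mayne & Englander, Proteins 17:75-86, 1993,
# and the accompanying spreadsheet lineage; see also Connelly et al. 1993 and
# Nguyen, Mayne, Phillips & Englander, JASMS 29:1936-1939, 2018).
# Columns:
#   residue    one-letter code; special rows N_TERM / C_TERM are terminal
#              corrections applied to the amide of residue 2 and of the
#              C-terminal residue respectively.
#   acid_prev  factor when this residue PRECEDES the exchanging amide (acid limb)
#   acid_self  factor when the exchanging amide is this residue's own NH (acid limb)
#   base_prev  factor when this residue PRECEDES the exchanging amide (base limb)
#   base_self  factor when the exchanging amide is this residue's own NH (base limb)
# Ionizable side chains (D, E, H) are tabulated in their dominant form for the
# near-neutral pD range (pD 5-9) this package targets: D/E carboxylates ionized,
# H neutral. Proline rows apply only in the "prev" role (trans isomer); the
# proline amide itself has no exchangeable hydrogen.
residue	acid_prev	acid_self	base_prev	base_self
A	0.00	0.00	0.00	0.00
R	-0.59	-0.32	0.08	0.22
N	-0.58	-0.13	0.49	0.32
D	0.90	0.58	0.10	-0.18
C	-0.54	-0.46	0.62	0.55
Q	-0.47	-0.27	0.06	0.20
E	-0.90	0.31	-0.11	-0.15
G	-0.22	0.22	-0.03	0.17
H	0.00	0.00	-0.10	0.14
I	-0.91	-0.59	-0.73	-0.23
L	-0.57	-0.13	-0.58	-0.21
K	-0.56	-0.29	-0.04	0.12
M	-0.64	-0.28	-0.01	0.11
F	-0.52	-0.43	-0.24	0.06
P	0.00	0.00	0.00	0.00
S	-0.44	-0.39	0.37	0.30
T	-0.79	-0.47	-0.07	0.20
W	-0.40	-0.44	-0.41	-0.11
Y	-0.41	-0.37	-0.27	0.05
V	-0.74	-0.30	-0.70	-0.14
N_TERM	-1.32	0.00	1.62	0.00
C_TERM	0.00	0.96	0.00	-1.80
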