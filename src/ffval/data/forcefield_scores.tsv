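force_field	year	s_folded	s_peptides	s_folding
ff99SB-ILDN	2010	0	1	0
ff99SB*-ILDN	2010	0	0	0
ff03	2003	1	2	1
ff03*	2009	1	1	0
OPLS-AA	2001	2	1	1
CHARMM22	1998	2	1	2
CHARMM27	2004	0	2	1
CHARMM22*	2011	0	0	0
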