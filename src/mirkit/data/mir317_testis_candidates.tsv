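gene_id	gene_name	log2fc	padj	biotype
FBgn0037427	Osi17	1.29	4.12E-09	coding
FBgn0037419	Osi12	1.22	2.53E-08	coding
FBgn0039178	CG6356	1.05	2.63E-11	coding
FBgn0066114	GlcAT-I	1.02	9.05E-11	coding
FBgn0036661	CG9705	0.81	1.03E-21	coding
FBgn0037845	CG14694	0.79	1.62E-04	coding
FBgn0267337	rn	0.69	3.58E-11	coding
FBgn0031001	CG7884	0.68	1.44E-03	coding
FBgn0034789	PIP5K59B	0.67	3.30E-03	coding
FBgn0036725	CG18265	0.67	2.46E-03	coding
FBgn0037555	Ada2b	0.61	6.22E-07	coding
FBgn0039064	CG4467	0.58	2.93E-02	coding
FBgn0037837	CG14693	0.56	3.38E-08	coding
FBgn0031275	GABA-B-R3	0.54	1.98E-08	coding
FBgn0033476	oys	0.53	1.46E-09	coding
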