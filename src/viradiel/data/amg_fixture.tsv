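gene_id	contig_id	auxiliary_score	flags	kegg_ko	metabolic_module	in_viral_region	contig_virus_score	near_phage_end	trna_overlap	repeat_overlap	contig_annotations
g01	c01	2	M	K06217	1	1	0.99	0	0	0	phoH family protein
g02	c02	4	M	K02703	1	1	0.99	0	0	0	photosystem II
g03	c03	2	F	K05979	0	1	0.99	0	0	0	hypothetical
g04	c04	1	K	K07336	1	0	0.8	0	0	0	oxygenase
g05	c05	2	E	K00001	1	1	0.99	0	0	0	site-specific integrase; tail fiber
g06	c06	3	M	K00002	1	1	0.99	1	1	0	kinase
g07	c07	1	M		1	1	0.99	0	0	0	sulfatase
g08	c08	3	K	K09882	0	0	0.97	0	0	0	cobS
g09	c09	1	E	K00003	0	1	0.99	1	0	0	dehydrogenase
g10	c10	2	M	K00004	1	1	0.99	0	0	0	Glycosyltransferase family 2
g11	c11	2	V	K00005	1	1	0.99	0	0	0	reductase
g12	c12	1	M	K00006	1	1	0.6	0	0	0	transferase
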