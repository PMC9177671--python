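# Published candidate-SNP annotation for the pigeonpea days-to-flowering region on CcLG03
# (9 genic SNPs in 7 genes; high bulk = late-flowering pool, low bulk = early-flowering pool).
# coordinates: 1-based inclusive
chrom	gene	pos	ref	alt	index_high	index_low	delta	region	effect	codon_ref	codon_alt	function
CcLG03	C.cajan_09900	19222701	G	A	0	1	-1	exon	nsSNP	aCg	aTg	Pentatricopeptide repeat-containing protein
CcLG03	C.cajan_09938	19549631	A	G	0	1	-1	intron	non-coding			Chromodomain-helicase-DNA-binding protein 4
CcLG03	C.cajan_09958	19690312	G	A	0	1	-1	intron	non-coding			Maestro heat-like repeat-containing protein family
CcLG03	C.cajan_09965	19763754	C	T	0	1	-1	intron	non-coding			Phosphatidylinositol 4-phosphate 5-kinase 9
CcLG03	C.cajan_10046	20439904	G	C	0	1	-1	intron	non-coding			1,4-alpha-glucan-branching enzyme
CcLG03	C.cajan_10067	20635496	T	A	0	1	-1	intron	non-coding			Uridine nucleosidase 1
CcLG03	C.cajan_10078	20745506	G	T	0	1	-1	exon	sSNP			Cell division protein
CcLG03	C.cajan_10078	20745771	A	G	0	1	-1	intron	non-coding			Cell division protein
CcLG03	C.cajan_10078	20747419	C	T	0	1	-1	intron	non-coding			Cell division protein
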