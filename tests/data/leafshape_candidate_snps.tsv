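# Published candidate-SNP annotation for the pigeonpea obcordate-leaf-shape region on CcLG08
# (39 genic SNPs in 20 genes; high bulk = obcordate pool, low bulk = lanceolate pool).
# One row's delta column is printed truncated in the source table and is transcribed as -1,
# consistent with the delta = -1 selection rule applied to every listed SNP.
# coordinates: 1-based inclusive
chrom	gene	pos	ref	alt	index_high	index_low	delta	region	effect	codon_ref	codon_alt	function
CcLG08	C.cajan_15985	6701814	A	T	0	1	-1	intron	non-coding			Beta-carotene hydroxylase 2
CcLG08	C.cajan_15991	6764651	T	C	0	1	-1	exon	nsSNP	Tgt	Cgt	Ac-like transposase
CcLG08	C.cajan_16002	6915910	T	C	0	1	-1	exon	nsSNP	aTg	aCg	Uncharacterized protein
CcLG08	C.cajan_16003	6921340	A	G	0	1	-1	exon	sSNP			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6923929	T	C	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6924854	A	G	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6927480	C	T	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6927533	A	G	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6927560	T	C	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16003	6927678	T	C	0	1	-1	intron	non-coding			Pro-Pol polyprotein
CcLG08	C.cajan_16012	7057478	G	A	0	1	-1	exon	nsSNP	Gca	Aca	F-box protein
CcLG08	C.cajan_16012	7059171	T	C	0	1	-1	intron	non-coding			F-box protein
CcLG08	C.cajan_16013	7068488	G	C	0	1	-1	intron	non-coding			Uncharacterized protein
CcLG08	C.cajan_16013	7068679	G	A	0	1	-1	intron	non-coding			Uncharacterized protein
CcLG08	C.cajan_16013	7070780	C	T	0	1	-1	exon	nsSNP	cCt	cTt	Uncharacterized protein
CcLG08	C.cajan_16014	7083922	T	A	0	1	-1	intron	non-coding			Transcriptional corepressor
CcLG08	C.cajan_16014	7093751	G	A	0	1	-1	intron	non-coding			Transcriptional corepressor
CcLG08	C.cajan_16038	7456634	T	C	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16038	7456764	A	G	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16038	7456831	T	A	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16038	7456974	A	G	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16038	7457844	C	A	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16041	7486941	A	G	0	1	-1	intron	non-coding			Uncharacterized protein
CcLG08	C.cajan_16047	7606346	T	A	0	1	-1	intron	non-coding			Transposon Ty3-I
CcLG08	C.cajan_16049	7641790	A	C	0	1	-1	intron	non-coding			E3 ubiquitin-protein ligase
CcLG08	C.cajan_16049	7642733	G	A	0	1	-1	intron	non-coding			E3 ubiquitin-protein ligase
CcLG08	C.cajan_16049	7643315	A	C	0	1	-1	exon	sSNP			E3 ubiquitin-protein ligase
CcLG08	C.cajan_16051	7666784	A	G	0	1	-1	intron	non-coding			Protein ROOT PRIMORDIUM DEFECTIVE 1
CcLG08	C.cajan_16051	7667174	T	C	0	1	-1	intron	non-coding			Protein ROOT PRIMORDIUM DEFECTIVE 1
CcLG08	C.cajan_16059	7780600	A	T	0	1	-1	intron	non-coding			Probable methyltransferase PMT16
CcLG08	C.cajan_16061	7838639	C	T	0	1	-1	exon	sSNP			1-aminocyclopropane-1-carboxylate oxidase homolog 1
CcLG08	C.cajan_16062	7870949	A	G	0	1	-1	intron	non-coding			Uncharacterized protein
CcLG08	C.cajan_16063	7888623	G	A	0	1	-1	intron	non-coding			1-aminocyclopropane-1-carboxylate oxidase homolog 12
CcLG08	C.cajan_16066	7940765	C	G	0	1	-1	intron	non-coding			Tripeptidyl-peptidase 2
CcLG08	C.cajan_16066	7947009	G	A	0	1	-1	intron	non-coding			Tripeptidyl-peptidase 2
CcLG08	C.cajan_16066	7950673	A	C	0	1	-1	intron	non-coding			Tripeptidyl-peptidase 2
CcLG08	C.cajan_16068	8008253	C	A	0	1	-1	intron	non-coding			Cytochrome P450
CcLG08	C.cajan_16074	8168767	C	A	0	1	-1	intron	non-coding			Type I inositol
CcLG08	C.cajan_16099	8666995	T	C	0	1	-1	exon	sSNP			-
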