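pos	ref	alt	category	source
3243	A	G	tRNA_confirmed	curated:tRNA-Leu(UUR) MELAS
3460	G	A	confirmed_pathogenic_missense	curated:ND1 LHON
3565	A	AC	benign/unknown	curated:ND1 frameshift-context (classified structurally)
5628	T	C	tRNA_likely	curated:tRNA-Ala
8344	A	G	tRNA_confirmed	curated:tRNA-Lys MERRF
8363	G	A	tRNA_likely	curated:tRNA-Lys
11778	G	A	confirmed_pathogenic_missense	curated:ND4 LHON
14484	T	C	confirmed_pathogenic_missense	curated:ND6 LHON
15924	A	G	tRNA_possibly	curated:tRNA-Thr
16189	T	C	benign/unknown	curated:D-loop polymorphism
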