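locus_tag	length_bp	product
RS16150	279	Veg family protein
RS07500	669	PilZ domain-containing protein
RS17880	663	M23 family metallopeptidase
RS05630	1098	polysaccharide pyruvyl transferase CsaB
RS02655	1101	D-alanine--D-alanine ligase
RS16455	1275	UDP-N-acetylglucosamine 1-carboxyvinyl transferase
RS13520	1506	UDP-N-acetylmuramoyl-L-alanyl-D-glutamate--2,6-diaminopimelate ligase
RS08320	768	ABC transporter permease
RS09880	1032	ABC transporter substrate-binding protein
RS07025	1095	YeeE/YedE family protein
RS12640	1797	ATP-dependent zinc metalloprotease FtsH
RS06785	636	guanylate kinase
RS00715	813	NAD(P) binding domain-containing protein
RS14505	1461	IMP dehydrogenase
RS16105	570	aminoacyl-tRNA hydrolase
RS17470	624	helix-turn-helix transcriptional regulator
RS09835	702	RNA polymerase sporulation sigma factor SigK
RS16160	858	16S rRNA (adenine(1518)-N(6)/adenine(1519)-N(6))-dimethyltransferase RsmA
RS05755	1227	tyrosine--tRNA ligase
RS12140	2562	single-stranded-DNA-specific exonuclease RecJ
RS07085	507	Hsp20/alpha crystallin family protein
RS09165	885	site-specific tyrosine recombinase XerD
RS02780	1293	glycoside hydrolase family 18 protein
RS18735	210	hypothetical protein
RS11335	246	hypothetical protein
RS09245	447	hypothetical protein
RS18275	558	hypothetical protein
RS14425	666	hypothetical protein
RS18470	672	hypothetical protein
RS06565	921	hypothetical protein
RS01700	921	hypothetical protein
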