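nearest_gene	tad_genes	sequence	motif_type	rodent	human	bird	reptile	frog	fish	region	element_class
C1d	none	GGGTCA G GGGTTA	DR1	x	x	x	x	x	x	chr11:18748180-18748192	enhancer
Clstn1	Lzic,Nmnat1,Kif1b	GGGTCA GA AGGTCA	DR2	x	x	x	x	x		chr4:149907094-149907107	enhancer
Dach1	none	AGTTCA CACAA AGTTCA	DR5	x	x	x	x	x	x	chr14:98035388-98035404	enhancer
Dhrs3	none	GGGTCA TTCCA AGTTCA	DR5	x	x	x	x	x		chr4:145034810-145034826	enhancer
Dhrs3	none	GGTTCA TCGGG AGGGCA	DR5	x	x	x	x	x		chr4:145034847-145034863	enhancer
Foxp4	none	GGGTGA C AGGTCA	DR1	x	x	x	x			chr17:47898625-47898637	enhancer
Hoxa1	Hoxa4,Hoxa9,Skap2	GGTTCA CCGAA AGTTCA	DR5	x	x	x	x	x		chr6:52153426-52153442	enhancer
Hoxa1	Hoxa4,Hoxa9,Skap2	GGTTCA AGAAG AGTTCA	DR5	x	x	x	x	x	x	chr6:52175533-52175549	enhancer
Meis1	none	AGGCCA CTGAG AGGTCA	DR5	x	x	x	x	x		chr11:18963875-18963891	enhancer
Meis2	Dph6	AGGTCA AAAAC AGTTCA	DR5	x	x	x	x			chr2:116071242-116071258	enhancer
Nr2f1	none	GTGTCA A AGTTCA	DR1	x	x	x	x	x	x	chr13:78200425-78200437	enhancer
Nr2f2	none	GTGTCA A AGTTCA	DR1	x	x	x	x	x	x	chr7:70361772-70361784	enhancer
Pbx1	Lmx1a	GGGTCG CT GGGTCA	DR2	x	x	x	x			chr1:169238844-169238857	enhancer
Rarb	none	GGTTCA CCGAA AGTTCA	DR5	x	x	x	x			chr14:16575513-16575529	enhancer
Sox2	none	GGGTCA GG AGGTCA	DR2	x	x	x	x	x	x	chr3:34679067-34679080	enhancer
Tshz1	none	GGGTCA TTCAT AGTTCA	DR5	x	x	x	x			chr18:84073476-84073492	enhancer
Tshz1	none	AGGTCA GG AGGTGA	DR2	x	x	x	x			chr18:83839858-83839871	enhancer
Tshz1	none	GGGTGA ACTCA GGTTCA	DR5	x	x	x	x			chr18:83839869-83839885	enhancer
Zbtb16	none	GGGTCA CA GGGTCA	DR2	x	x	x	x	-	x	chr9:48694721-48694734	enhancer
Zbtb16	none	GGGTCA G GGGTTA	DR1	x	x	x	x			chr9:48695827-48695839	enhancer
Zfhx4	Pex2	GGGTCA GCCTG AGGTCA	DR5	x	x	x	x	x	x	chr3:5388103-5388119	enhancer
Zfp386	none	GAGTCA A AGGTCA	DR1	x	-	x	x			chr12:117352086-117352098	enhancer
Zfp638	none	GGTTCA GCCAA AGGTGA	DR5	x	x	x	x	x		chr6:84976840-84976856	enhancer
Fgf8	Poll,Btrc,Mrpl43,Chuk,Sema4g,Dnmbp,Erlin1,Entpd7,Got1,Slc25a28	GGGTCA GC AGTTCA	DR2	x	x	x				chr19:45747043-45747056	silencer
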