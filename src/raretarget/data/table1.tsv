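mark	region	peak_log2fc	rare_types	gene	rna_log2fc
H3K27ac	chr13:78197222-78204291	-1.23	DR1	Nr2f1	-2.02
H3K27ac	chr4:145033496-145035860	-0.65	DR5	Dhrs3	-1.11
H3K27ac	chr14:16571405-16576397	-0.63	DR5	Rarb	-1.64
H3K27ac	chr11:18962656-18965461	-0.61	DR5,DR1	Meis1	-2.64
H3K27ac	chr2:105689278-105690982	-0.58	-	Pax6	-3.02
H3K27ac	chr3:87956774-87961235	-0.58	DR2,DR1	Crabp2	-2.82
H3K27ac	chr2:116019003-116024272	-0.58	DR2	Meis2	-1.10
H3K27ac	chr7:70348715-70369942	-0.57	DR1	Nr2f2	-2.32
H3K27ac	chr11:18956989-18958835	-0.57	DR5	Meis1	-2.64
H3K27ac	chr11:19012000-19025444	-0.54	DR1	Meis1	-2.64
H3K27ac	chr3:34678267-34680699	-0.54	DR2	Sox2	-0.86
H3K27ac	chr18:61033064-61036494	-0.52	DR2,DR1	Cdx1	-2.00
H3K27ac	chr3:34647848-34655776	-0.51	-	Sox2	-0.86
H3K27ac	chr19:45733505-45735997	0.53	DR1	Fgf8	5.24
H3K27ac	chr13:114456392-114460659	0.72	DR2	Fst	1.15
H3K27ac	chr5:147298587-147311126	0.73	DR2	Cdx2	1.98
H3K27me3	chr18:38598986-38601292	-1.20	-	Spry4	3.43
H3K27me3	chr5:147297983-147318733	-0.63	DR2	Cdx2	1.98
H3K27me3	chr19:45735049-45746658	-0.49	DR2	Fgf8	5.24
H3K27me3	chr13:114456076-114460873	-0.47	DR2	Fst	1.15
H3K27me3	chr4:144893360-144895562	0.59	-	Dhrs3	-1.11
H3K27me3	chr2:116072251-116077455	0.61	DR5	Meis2	-1.10
H3K27me3	chr7:70356085-70361002	0.63	DR1	Nr2f2	-2.32
H3K27me3	chr6:52156115-52158253	0.73	DR5,DR2	Hoxa1	-5.43
H3K27me3	chr11:19015536-19017169	0.78	DR1	Meis1	-2.64
H3K27me3	chr11:19007512-19012358	0.87	DR2	Meis1	-2.64
H3K27me3	chr14:16574377-16578138	1.02	DR5,DR1	Rarb	-1.64
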