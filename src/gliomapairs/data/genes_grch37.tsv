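gene	chrom	start	end
MTOR	chr1	11166588	11322608
PIK3R3	chr1	46505812	46642163
H3F3A	chr1	226249396	226259211
IDH1	chr2	209100951	209119806
ACVR1	chr2	158592958	158732374
MLH1	chr3	37034823	37092337
PIK3CA	chr3	178866311	178952497
PDGFRA	chr4	55095264	55164412
RAD50	chr5	131892979	131980313
HIST1H3B	chr6	26031817	26032288
EGFR	chr7	55086714	55324313
BRAF	chr7	140419127	140624564
CDKN2A	chr9	21967751	21995300
ZMYND11	chr10	180405	264868
CDH11	chr16	64943753	65126112
TP53	chr17	7571720	7590868
NF1	chr17	29421945	29709134
PPM1D	chr17	58677544	58743037
CDH1	chr16	68771128	68869444
ERBB2	chr17	37844167	37886679
ERBB4	chr2	212240442	213403352
FLT1	chr13	28874489	29069265
EPHA2	chr1	16450832	16482582
EPHB2	chr1	23037331	23241769
ITGA2	chr5	52285876	52391190
ITGB4	chr17	73717516	73753899
EP300	chr22	41488614	41576081
LZTR1	chr22	21333751	21353326
PIK3CD	chr1	9711790	9789172
ATRX	chrX	76760356	77041719
BCOR	chrX	39909068	40036582
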