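patient_id	molecular_group	age_years	sex	primary_dx	recurrence_dx	ttp_months	interval_months	location	sublocation	surgery1	surgery2	germline_available	treatments
HGG1	H3/IDH1 mutant	14	M	GBM	GBM	8.7	16.2	midline	Spine	GTR	NA (autopsy)	Yes	RT+ TMZ, TMZ
HGG2	H3/IDH1 mutant	18	F	AA	GBM	10.3	14.4	midline	Pons	STR	NA (autopsy)	Yes	RT+ TMZ, TMZ, bevacizumab, vorinostat
HGG3	H3/IDH1 mutant	13	F	GBM	GBM	6.5	6.5	midline	Spine	STR	NA (autopsy)	Yes	RT+ TMZ, rapamycin
HGG4	H3/IDH1 mutant	4	F	GBM	GBM	23.5	23.5	midline	Pons	Biopsy	NA (autopsy)	No	RT + vandatenib, dasatinib
HGG5	H3/IDH1 mutant	12	M	GBM	GBM	7.1	8.7	hemisphere		GTR	NA (autopsy)	No	RT + TMZ, TMZ + bevacizumab
HGG6	H3/IDH1 mutant	29	F	AA focal GBM	GBM	45.2	45.2	hemisphere		STR	STR	No	RT + TMZ, TMZ
HGG7	H3/IDH1 mutant	19	F	AA	AA	14.3	14.3	hemisphere		GTR	GTR	No	Surgery
HGG8	H3/IDH1 wildtype	15	F	AA	GBM	12	13	midline	Thalamus	Biopsy	NA (autopsy)	Yes	RT+ bevacizumab + TMZ, bevacizumab + TMZ + irinotecan
HGG9	H3/IDH1 wildtype	18	M	GBM	GBM	25.3	25.3	hemisphere		GTR	STR	Yes	RT, bevacizumab + irinotecan
HGG10	H3/IDH1 wildtype	10	F	HGG Gr III w neuronal component	HGG Gr IV w neuronal component	9.3	17.3	hemisphere		GTR	STR	Yes	RT, lapatinib + bevacizumab, VP16
HGG11	H3/IDH1 wildtype	14	F	GBM	GBM	3.8	7.1	hemisphere		Biopsy	NA (autopsy)	Yes	RT + TMZ, bevacizumab
HGG12	H3/IDH1 wildtype	17	M	GBM	GBM	29.1	29.1	hemisphere		STR	STR	No	RT, VP16, BMT
HGG13	H3/IDH1 wildtype	19	M	AA	AA	39.2	39.2	hemisphere		GTR	GTR	No	RT+ TMZ, TMZ
HGG14	H3/IDH1 wildtype	12	M	GBM	GBM	13.8	13.8	hemisphere		GTR	GTR	No	RT + TMZ, TMZ + lomustine
HGG15	NF1 germline	15	M	AA	GBM	42.4	65.4	hemisphere		GTR	NA (autopsy)	Yes	RT, cisplatin + cyclophosphamide + topotecan + vincristine, TMZ, bevacizumab, rapamycin, cabozantinib
HGG16	NF1 germline	23	F	LGG Gr II w pilocytic features	GBM	9.5	9.5	hemisphere		GTR	STR	Yes	Surgery
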