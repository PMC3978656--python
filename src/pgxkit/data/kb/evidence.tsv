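subject	gene	drug	study_category	drug_target	finding	qualifier	is_private	sample_size	effect_point	effect_lo	effect_hi
*2	CYP2C19	clopidogrel	clinical_outcomes	drug_of_interest	consistent_effect		false	1477	1.53	1.07	2.19
*17	CYP2C19	clopidogrel	clinical_outcomes	drug_of_interest	consistent_effect		false	1250
*2	CYP2C19	PPIs	clinical_outcomes	drug_of_interest	consistent_effect		false	300
*17	CYP2C19	PPIs	pk_pd	drug_of_interest	consistent_effect		false	120
*8	CYP2C19	clopidogrel	molecular_cellular	probe_drug	consistent_effect		false	40
*6	CYP2C19	clopidogrel	molecular_cellular	probe_drug	consistent_effect	scd	false	12
*3	CYP2C9	celecoxib	clinical_outcomes	drug_of_interest	consistent_effect		false	45
*2	CYP2C9	celecoxib	pk_pd	drug_of_interest	consistent_effect		false	60
*2	CYP2C9	warfarin	clinical_outcomes	drug_of_interest	consistent_effect		false	2000
*3	CYP2C9	warfarin	clinical_outcomes	drug_of_interest	consistent_effect		false	2000
*14	CYP2C9	warfarin	screening		insufficient		false
A	VKORC1	warfarin	clinical_outcomes	drug_of_interest	consistent_effect		false	1500
A	CYP4F2	warfarin	clinical_outcomes	drug_of_interest	consistent_effect		false	900
*4	CYP2D6	codeine	clinical_outcomes	drug_of_interest	consistent_effect		false	170
*1xN	CYP2D6	codeine	clinical_outcomes	drug_of_interest	consistent_effect		false	25
*41	CYP2D6	tamoxifen	clinical_outcomes	drug_of_interest	inconsistent		false	1300
*2	TPMT	thiopurines	clinical_outcomes	drug_of_interest	consistent_effect		false	350
*3A	TPMT	thiopurines	clinical_outcomes	drug_of_interest	consistent_effect		false	350
V174A	SLCO1B1	simvastatin	clinical_outcomes	drug_of_interest	consistent_effect		false	85
*6	SLCO1B1	simvastatin	pk_pd	other_drug	consistent_effect	ad	false	30
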