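category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM		Expected to respond to a standard dose of thiopurine drugs; not at increased risk of drug toxicity. Normal enzymatic function and normal drug elimination		*1/*1	94	81	97
IM	IM		At increased risk of drug toxicity such as myelosuppression when taking standard dose of thiopurine drugs; risk of side effects can be reduced by reducing the standard dose by 50 to 70%. Reduced enzymatic function leading to reduced drug elimination and greater drug exposure	Heterozygous patients with low or intermediate TPMT activity are more likely to experience toxicity	*1/*2;*1/*3A	6	18	3
PM	PM		At increased risk of drug toxicity such as myelosuppression when taking thiopurine drugs; should consider alternative medication. Very low or absent enzymatic function leading to greatly reduced drug elimination and increased drug exposure	Homozygous-deficient patients (two non-functional TPMT alleles) given the usual dose of thiopurines are at increased risk of toxicity	*3A/*3A;*3B/*3B	0.1	1	0
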