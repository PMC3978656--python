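category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM		Likely to have a normal response to standard dose of clopidogrel; normal enzymatic function and normal drug activation; normal platelet inhibition		*1/*1	38	36	35.5
IM	IM		Increased risk of ischemic event while on clopidogrel; reduced enzymatic function resulting in reduced drug activation and decreased platelet inhibition. Should use alternative anti-platelet medication		*1/*2;*1/*8	19	22	46
PM	PM		Increased risk of ischemic event while on clopidogrel; greatly reduced or abolished enzymatic function leading to little or no drug activation and greatly diminished platelet inhibition. Should use alternative anti-platelet medication	CYP2C19 PMs with ACS or undergoing PCI treated with clopidogrel at recommended doses exhibit higher cardiovascular event rates than patients with normal CYP2C19 function. Consider alternative treatment or treatment strategies in patients identified as CYP2C19 PMs	*2/*2	2	3	15
UM	UM		Possible increased risk of bleeding, but also likely to derive greater protection from ischemic event while on clopidogrel; enhanced enzymatic function leading to greater drug activation		*1/*17;*17/*17	34	31	2
UNK	unknown		Unknown effect on drug response; metabolizer status undetermined. PD data indicate platelet response intermediate between likely IMs and EMs		*2/*17	7	8	1.5
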