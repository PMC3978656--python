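category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM		Expected to have a normal response at standard dose of warfarin; normal enzymatic function and normal drug elimination	The warfarin drug label includes a table of genotype-based therapeutic dosing guidelines giving the range of expected therapeutic doses for combinations of the VKORC1 -1639G>A genotype and the CYP2C9 *2 and *3 variants	*1/*1	67	76	88
IM	IM		At increased risk of bleeding at standard dose of warfarin; takes longer to reach therapeutic INR and requires lower dose. Reduced enzymatic function leading to reduced drug elimination and greater drug exposure		*1/*2;*1/*14	20	17	4
PM	PM		At increased risk of bleeding at standard dose of warfarin; takes longer to reach therapeutic INR and requires lower dose. Greatly reduced enzymatic function leading to greatly increased drug exposure		*1/*3;*2/*2;*2/*3;*3/*3	13	7	8
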