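category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
GG	custom		Associated with a requirement for lower therapeutic warfarin dose; potentially at increased risk of bleeding events. Higher CYP4F2 activity results in reduced hepatic vitamin K levels		G/G	53	83	63
GA	custom		Associated with a requirement for intermediate therapeutic warfarin dose. Intermediate CYP4F2 activity results in intermediate hepatic vitamin K levels		G/A	40	16	33
AA	custom		Associated with a requirement for higher therapeutic warfarin dose; potentially at increased risk of thrombosis at standard dose. Reduced CYP4F2 activity results in increased hepatic vitamin K levels		A/A	7	1	4
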