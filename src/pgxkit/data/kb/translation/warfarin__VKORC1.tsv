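category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
GG	custom		Associated with a requirement for higher therapeutic warfarin dose; potentially at increased risk of thrombosis at standard dose. Normal mRNA expression, normal enzyme activity and efficient vitamin K cycling		G/G	40	74	1
GA	custom		Associated with a requirement for intermediate therapeutic warfarin dose. Reduced mRNA expression, reduced enzyme activity and vitamin K cycling		G/A	47	24	20
AA	custom		Associated with a requirement for lower therapeutic warfarin dose; potentially at increased risk of bleeding events. Greatly reduced mRNA expression and significant reduction in enzyme activity and vitamin K cycling		A/A	13	2	79
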