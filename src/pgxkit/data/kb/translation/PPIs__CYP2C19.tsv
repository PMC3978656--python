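category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM		Likely to have normal response to standard dose of PPIs; normal enzymatic function and normal drug elimination		*1/*1	38	35	35
IM	IM		Likely to have improved PPI efficacy at standard dose as measured by intragastric pH, duration of inhibition, and cure rates for GERD and Helicobacter pylori; reduced enzymatic function leading to reduced drug elimination and greater drug exposure		*1/*2;*1/*8;*2/*17	26	31	48
PM	PM		Likely to have improved PPI efficacy at standard dose; greatly reduced or abolished enzymatic function leading to reduced drug elimination and greater drug exposure		*2/*2	2	3.5	15
UM	UM		Decreased PPI efficacy at standard doses; enhanced enzymatic function leading to greater drug elimination and reduced drug exposure		*17/*17	5	4.5	0.04
UNK	unknown		Unknown effect on drug response; metabolizer status undetermined. PD data show platelet response intermediate between IMs and EMs		*1/*17	29	26	2
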