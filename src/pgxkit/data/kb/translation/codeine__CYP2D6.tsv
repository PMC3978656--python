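category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM	normal	Normal analgesic response to standard dose of codeine; normal enzymatic function and normal conversion of codeine to morphine		*1/*1;*1/*3;*1/*4;*1/*5;*1/*6;*1/*7;*1/*9;*1/*10	80	69	45
IM	IM	reduced	Reduced analgesic response (pain relief); may require an increased dose to obtain an analgesic effect or should consider alternative pain medication. Reduced enzymatic function leading to reduced conversion of codeine to morphine		*4/*41;*4/*9;*4/*10;*41/*41;*5/*41;*9/*41;*10/*41	12	26	26
PM	PM	none	Little or no analgesic response (pain relief); should consider alternative pain medication. Greatly reduced or abolished enzymatic function leading to greatly reduced conversion of codeine to morphine		*3/*4;*4/*4;*4/*5;*4/*7	8	3	14
UM	UM	increased	Increased risk of drug toxicity and ADRs; should consider alternative pain medication. Enhanced enzymatic function leading to greater conversion of codeine to morphine and higher drug exposure	CYP2D6 PMs and UMs may experience different efficacy. Even at labeled dosage regimens UMs may experience overdose symptoms; use of codeine by UM mothers can potentially lead to serious ADRs, including death, in nursing infants	*1/*1xN;*1xN/*1xN;*1xN/*4;*1xN/*5;*1xN/*10;*1xN/*36	<0.1	2	15
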