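gene	rsid	nucleotide_change	mutation_type	freq_caucasian	freq_african	freq_eastasian
CYP2C19	rsV2	681G>A	scd	0.15	0.17	0.29
CYP2C19	rsV8	358T>C		0.003	0.002	0.001
CYP2C19	rsV17	-806C>T	ae	0.22	0.19	0.01
CYP2C19	rsV6	395G>A		0.001	0.001	0.001
CYP2C9	rsW2	430C>T		0.13	0.03	0.01
CYP2C9	rsW3	1075A>C		0.07	0.02	0.04
CYP2C9	rsW14	374G>A		0.002	0.05	0.001
CYP2D6	rsD3	2549A>G	n	0.01	0.005	0.001
CYP2D6	rsD4	1846G>A	scd	0.19	0.08	0.005
CYP2D6	rsD5	1023C>T	n	0.03	0.06	0.06
CYP2D6	rsD6	1707T>C	n	0.01	0.005	0.001
CYP2D6	rsD7	2935A>C	n	0.001	0.001	0.001
CYP2D6	rsD9	2615A>G		0.03	0.01	0.01
CYP2D6	rsD10	100C>T		0.02	0.07	0.42
CYP2D6	rsD41	2988G>A		0.09	0.11	0.03
CYP2D6	rsD36	4180G>C		0.001	0.005	0.02
TPMT	rsT2	238G>C		0.002	0.005	0.001
TPMT	rsT460	460G>A		0.03	0.05	0.01
TPMT	rsT719	719A>G		0.03	0.04	0.01
SLCO1B1	rsS174	521T>C		0.16	0.02	0.12
SLCO1B1	rsS6	455G>A		0.02	0.02	0.005
SLCO1B1	rsS3	383A>G		0.01	0.01	0.005
VKORC1	rs9923231	-1639G>A	ae	0.37	0.14	0.89
CYP4F2	rsV433M	1297G>A		0.27	0.09	0.21
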