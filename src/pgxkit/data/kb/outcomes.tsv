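drug	genes	status	reason	highly_actionable
warfarin	CYP2C9;VKORC1;CYP4F2	approved		CYP2C9:PM;VKORC1:AA
warfarin	GGCX	rejected	Insufficient clinical support for GGCX at time of submission evaluation
clopidogrel	CYP2C19	approved		PM
tamoxifen	CYP2D6	deferred	Data linking prognostic and predictive relevance of CYP2D6 variants to guide tamoxifen therapy were inconclusive; vote deferred pending publication of anticipated clinical trials data
codeine	CYP2D6	approved		UM
metoprolol	CYP2D6	rejected	Lack of clinical evidence; given prescribing practices the genetic results are unlikely to influence drug dose adjustment
thiopurines	TPMT	approved		IM;PM
PPIs	CYP2C19	approved
diazepam	CYP2C19	rejected	Evidence for clinical consequences is weak
celecoxib	CYP2C9	approved		*3/*3
simvastatin	SLCO1B1	approved		decreased_transport
statins	CYP3A4;CYP3A5	deferred	Deferred pending further clinical data
statins	LDLR;HMGCR	rejected	Evidence for clinical utility is lacking
fluorouracil	DPYD	rejected	Recent evidence for lower penetrance of reduced activity variants combined with a lack of good alternative treatment reduces the clinical utility of the PGx information
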