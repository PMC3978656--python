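drug	gene	fallback_policy
clopidogrel	CYP2C19	lookup_only
PPIs	CYP2C19	lookup_only
celecoxib	CYP2C9	lookup_only
warfarin	CYP2C9	lookup_only
warfarin	VKORC1	lookup_only
warfarin	CYP4F2	lookup_only
codeine	CYP2D6	highest_function_allele
thiopurines	TPMT	lookup_only
simvastatin	SLCO1B1	lookup_only
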