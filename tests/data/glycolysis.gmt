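GLYCOLYSIS_CURATED	core glycolytic enzymes and transporters (curated)	HK1	HK2	GPI	PFKL	PFKM	ALDOA	TPI1	GAPDH	PGK1	PGAM1	ENO1	PKM	LDHA	SLC2A1	SLC16A1
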