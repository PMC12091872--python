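chrom	start	end	direction	fdr_tier	log2fc	id
chrA	1000	1600	UP	0.05	1.21	pk1
chrA	5000	5400	UP	0.001	2.02	pk2
chrB	2000	2500	DOWN	0.01	-0.88	pk3
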