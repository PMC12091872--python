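chrA	1000	1600	pk1	0	.	UP	0.05	1.21
chrA	5000	5400	pk2	0	.	UP	0.001	2.02
chrB	2000	2500	pk3	0	.	DOWN	0.01	-0.88
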