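chr2L	23513712
chr2R	25286936
chr3L	28110227
chr3R	32079331
chr4	1348131
chrX	23542271
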