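# APPROXIMATE dm6 pericentromeric boundary configuration.
#
# These coordinates are illustrative round numbers chosen to place a
# centromere-proximal heterochromatin block on each major arm (right
# end of 2L/3L/X, left end of 2R/3R, all of chromosome 4) totalling
# ~19 Mb, i.e. ~14.2% of the 133,880,608 bp six-chromosome assembly.
# They are NOT the published epigenetic H3K9me2-transition coordinates;
# substitute measured boundaries before drawing biological conclusions
# from real dm6 data.
#
# Use together with examples/dm6_chrom_sizes.tsv.
boundaries:
  arms:
    - {chrom: chr2L, boundary: 21400000, side: RIGHT_OF_BOUNDARY}
    - {chrom: chr2R, boundary: 6000000, side: LEFT_OF_BOUNDARY}
    - {chrom: chr3L, boundary: 25800000, side: RIGHT_OF_BOUNDARY}
    - {chrom: chr3R, boundary: 4200000, side: LEFT_OF_BOUNDARY}
    - {chrom: chrX, boundary: 20500000, side: RIGHT_OF_BOUNDARY}
  whole_chromosomes: [chr4]
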