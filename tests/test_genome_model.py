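"""Genome representation: sizes, pericentromeric map, annotations, I/O."""

import pytest

from hetenrich.errors import ParseError, ValidationError
from hetenrich.genome_model import (
    ArmBoundary,
    BoundarySpec,
    ChromSizes,
    ChromatinState,
    ChromatinStateMap,
    CuratedRegionMap,
    GeneAnnotation,
    GeneRecord,
    Side,
    build_pericentromeric_map,
    load_chrom_sizes,
    load_curated,
    load_genes,
    load_states,
    write_chrom_sizes,
    write_curated,
    write_genes,
    write_states,
)


class TestChromSizes:
    def test_single_row(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chrT1\t1000000\n")
        sizes = load_chrom_sizes(p)
        assert sizes["chrT1"] == 1_000_000
        assert sizes.total_bp == 1_000_000

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("")
        with pytest.raises(ValidationError):
            load_chrom_sizes(p)

    def test_four_row_total(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("a\t1000000\nb\t800000\nc\t600000\nd\t200000\n")
        assert load_chrom_sizes(p).total_bp == 2_600_000

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("a\t100\na\t200\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_chrom_sizes(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("a\t100\nb\tnotanumber\n")
        with pytest.raises(ParseError, match=":2"):
            load_chrom_sizes(p)

    def test_round_trip(self, tmp_path, toy_sizes):
        p = tmp_path / "sizes.tsv"
        write_chrom_sizes(toy_sizes, p)
        assert dict(load_chrom_sizes(p)) == dict(toy_sizes)


class TestPericentromericMap:
    def test_whole_chromosome_flag(self):
        sizes = ChromSizes({"chrT4": 200_000})
        spec = BoundarySpec(whole_chromosomes=frozenset({"chrT4"}))
        pmap = build_pericentromeric_map(spec, sizes)
        assert list(pmap.intervals.records()) == [("chrT4", 0, 200_000)]
        assert pmap.total_bp == 200_000
        assert pmap.genome_fraction == 1.0

    def test_right_of_boundary_arm(self):
        sizes = ChromSizes({"chrT1": 1_000_000})
        spec = BoundarySpec(
            arms=(ArmBoundary("chrT1", 900_000, Side.RIGHT_OF_BOUNDARY),)
        )
        pmap = build_pericentromeric_map(spec, sizes)
        assert list(pmap.intervals.records()) == [("chrT1", 900_000, 1_000_000)]
        assert pmap.total_bp == 100_000

    def test_genome_fraction_quotient(self):
        # 19 Mb heterochromatin on a 133,880,608 bp genome -> 14.19...%
        sizes = ChromSizes({"chrA": 133_880_608})
        spec = BoundarySpec(
            arms=(ArmBoundary("chrA", 133_880_608 - 19_000_000, Side.RIGHT_OF_BOUNDARY),)
        )
        pmap = build_pericentromeric_map(spec, sizes)
        assert pmap.genome_fraction == pytest.approx(0.14192, abs=5e-6)

    def test_boundary_outside_chromosome(self):
        sizes = ChromSizes({"chrT1": 1_000})
        spec = BoundarySpec(arms=(ArmBoundary("chrT1", 2_000, Side.LEFT_OF_BOUNDARY),))
        with pytest.raises(ValidationError, match="outside"):
            build_pericentromeric_map(spec, sizes)

    def test_empty_spec_fraction_zero(self, toy_sizes):
        pmap = build_pericentromeric_map(BoundarySpec(), toy_sizes)
        assert pmap.genome_fraction == 0.0

    def test_all_flagged_fraction_one(self, toy_sizes):
        spec = BoundarySpec(whole_chromosomes=frozenset(toy_sizes))
        assert build_pericentromeric_map(spec, toy_sizes).genome_fraction == 1.0

    def test_arm_contributions_sum_exactly(self):
        sizes = ChromSizes({"a": 1_000_000, "b": 500_000, "c": 200_000})
        spec = BoundarySpec(
            arms=(
                ArmBoundary("a", 900_000, Side.RIGHT_OF_BOUNDARY),
                ArmBoundary("b", 50_000, Side.LEFT_OF_BOUNDARY),
            ),
            whole_chromosomes=frozenset({"c"}),
        )
        pmap = build_pericentromeric_map(spec, sizes)
        assert pmap.total_bp == 100_000 + 50_000 + 200_000

    def test_flagged_chromosome_with_boundary_rejected(self):
        with pytest.raises(ValidationError):
            BoundarySpec(
                arms=(ArmBoundary("c", 10, Side.LEFT_OF_BOUNDARY),),
                whole_chromosomes=frozenset({"c"}),
            )


class TestGeneAnnotation:
    def test_gff_tss_conversion_both_strands(self, tmp_path):
        # 1-based inclusive span 101-200: TSS is 100 (+) or 199 (-)
        p = tmp_path / "genes.gff"
        p.write_text(
            "chrA\tsrc\tgene\t101\t200\t.\t+\t.\tID=gplus\n"
            "chrA\tsrc\tgene\t101\t200\t.\t-\t.\tID=gminus\n"
        )
        ann = load_genes(p, dialect="gff")
        assert ann.tss_of("gplus") == ("chrA", 100)
        assert ann.tss_of("gminus") == ("chrA", 199)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("g1\tchrA\t+\t0\t100\ng1\tchrA\t+\t200\t300\n")
        with pytest.raises(ValidationError, match="g1"):
            load_genes(p, dialect="refflat")

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("g1\tchrA\t*\t0\t100\n")
        with pytest.raises(ValidationError, match="strand"):
            load_genes(p, dialect="refflat")

    def test_refflat_round_trip(self, tmp_path):
        ann = GeneAnnotation(
            [GeneRecord("g1", "c1", "+", 150), GeneRecord("g2", "c2", "-", 420)]
        )
        p = tmp_path / "genes.tsv"
        write_genes(ann, p)
        back = load_genes(p, dialect="refflat")
        assert {r.gene_id: (r.chrom, r.tss) for r in back.records} == {
            "g1": ("c1", 150),
            "g2": ("c2", 420),
        }


class TestChromatinStateMap:
    def test_single_red_segment(self, tmp_path):
        p = tmp_path / "states.bed"
        p.write_text("c1\t0\t1000\tRED\n")
        smap = load_states(p)
        assert smap.state_bp(ChromatinState.RED) == 1000

    def test_overlapping_segments_rejected(self, tmp_path):
        p = tmp_path / "states.bed"
        p.write_text("c1\t0\t100\tBLACK\nc1\t50\t150\tRED\n")
        with pytest.raises(ValidationError, match="overlap"):
            load_states(p)

    def test_unknown_state_name_rejected(self, tmp_path):
        p = tmp_path / "states.bed"
        p.write_text("c1\t0\t100\tMAUVE\n")
        with pytest.raises(ValidationError, match="MAUVE"):
            load_states(p)

    def test_case_insensitive_state_names(self, tmp_path):
        p = tmp_path / "states.bed"
        p.write_text("c1\t0\t100\tblack\n")
        assert load_states(p).state_bp(ChromatinState.BLACK) == 100

    def test_unassigned_complement(self):
        # colours cover 60% of a 1 Mb chromosome -> 40% unassigned
        sizes = ChromSizes({"c1": 1_000_000})
        smap = ChromatinStateMap(
            [
                ("c1", 0, 300_000, ChromatinState.BLACK),
                ("c1", 400_000, 700_000, ChromatinState.YELLOW),
            ],
            sizes=sizes,
        )
        unassigned = sizes.total_bp - smap.assigned_bp
        assert unassigned / sizes.total_bp == pytest.approx(0.4)

    def test_round_trip(self, tmp_path):
        smap = ChromatinStateMap(
            [("c1", 0, 100, ChromatinState.BLUE), ("c2", 5, 50, ChromatinState.GREEN)]
        )
        p = tmp_path / "states.bed"
        write_states(smap, p)
        back = load_states(p)
        assert sorted(back.segments) == sorted(smap.segments)


class TestCuratedRegionMap:
    def test_overlap_lookup_unions_genes(self):
        cmap = CuratedRegionMap(
            [
                ("c1", 0, 100, frozenset({"gA"})),
                ("c1", 50, 150, frozenset({"gB", "gC"})),
                ("c1", 500, 600, frozenset({"gD"})),
            ]
        )
        assert cmap.overlapping_genes("c1", 90, 120) == {"gA", "gB", "gC"}
        assert cmap.overlapping_genes("c1", 200, 300) == frozenset()
        assert cmap.overlapping_genes("c2", 0, 100) == frozenset()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValidationError):
            CuratedRegionMap([("c1", 0, 100, frozenset())])

    def test_round_trip(self, tmp_path):
        cmap = CuratedRegionMap(
            [("c1", 0, 100, frozenset({"gA", "gB"})), ("c2", 5, 50, frozenset({"gC"}))]
        )
        p = tmp_path / "curated.bed"
        write_curated(cmap, p)
        back = load_curated(p)
        assert sorted(back.records) == sorted(cmap.records)
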