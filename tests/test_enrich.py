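"""Enrichment statistics: contingency tables, chi-squared, BH, permutation."""

import numpy as np
import pytest
from scipy import stats

from hetenrich.enrich import (
    ContingencyTable2x2,
    bh_fdr,
    bp_contingency,
    chi2_test,
    enrichment_report,
    permutation_enrichment,
    updown_ratio,
)
from hetenrich.errors import ValidationError
from hetenrich.genome_model import ChromSizes
from hetenrich.intervals import IntervalSet, normalize
from hetenrich.peakio import Assay, Direction, PeakRecord, PeakTable


def closed_form_chi2(a, b, c, d):
    """Independent textbook formula: N(ad−bc)² / (r₁ r₂ c₁ c₂)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestBpContingency:
    def test_disjoint_query_and_region(self):
        sizes = ChromSizes({"c1": 10_000})
        query = normalize([("c1", 0, 100)])
        region = normalize([("c1", 5_000, 5_500)])
        t = bp_contingency(query, region, sizes)
        assert (t.a, t.b, t.c, t.d) == (0, 100, 500, 9_400)

    def test_query_inside_region_has_zero_b(self):
        sizes = ChromSizes({"c1": 10_000})
        t = bp_contingency(
            normalize([("c1", 100, 200)]), normalize([("c1", 0, 1_000)]), sizes
        )
        assert t.b == 0

    def test_cells_sum_to_genome_on_random_instances(self):
        rng = np.random.default_rng(3)
        sizes = ChromSizes({"c1": 10_000, "c2": 5_000})
        for _ in range(25):
            q = [
                ("c1", int(s), int(s) + int(rng.integers(1, 300)))
                for s in rng.integers(0, 9_000, size=10)
            ]
            r = [
                ("c2", int(s), int(s) + int(rng.integers(1, 300)))
                for s in rng.integers(0, 4_000, size=5)
            ] + [("c1", 0, int(rng.integers(1, 5_000)))]
            t = bp_contingency(normalize(q), normalize(r), sizes)
            assert t.total == sizes.total_bp

    def test_empty_query_rejected(self):
        sizes = ChromSizes({"c1": 10_000})
        with pytest.raises(ValidationError):
            bp_contingency(IntervalSet.empty(), normalize([("c1", 0, 10)]), sizes)


class TestChi2:
    def test_closed_form_example(self):
        stat, p = chi2_test(ContingencyTable2x2(30, 70, 100, 900))
        assert stat == pytest.approx(34.9, abs=0.05)
        assert stat == pytest.approx(closed_form_chi2(30, 70, 100, 900))
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_proportional_table_is_independent(self):
        stat, p = chi2_test(ContingencyTable2x2(10, 90, 100, 900))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_row_and_column_swap(self):
        t1 = ContingencyTable2x2(30, 70, 100, 900)
        t2 = ContingencyTable2x2(900, 100, 70, 30)  # both rows and columns swapped
        assert chi2_test(t1)[0] == pytest.approx(chi2_test(t2)[0])

    def test_matches_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 500, size=4))
            stat, _ = chi2_test(ContingencyTable2x2(a, b, c, d))
            assert stat == pytest.approx(closed_form_chi2(a, b, c, d), rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="permutation"):
            chi2_test(ContingencyTable2x2(0, 0, 5, 5))


def brute_force_bh(p):
    """Step-up BH computed literally from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBH:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.05])
        assert list(np.round(q, 10)) == [0.04, 0.04, 0.05, 0.05]

    def test_single_p(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        assert list(bh_fdr([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), brute_force_bh(p))


class TestUpdownRatio:
    def _table(self, n_up, n_down):
        recs = [
            PeakRecord("c1", 10 * i, 10 * i + 5, Direction.UP, 0.001, Assay.ATAC)
            for i in range(n_up)
        ] + [
            PeakRecord("c1", 100_000 + 10 * i, 100_000 + 10 * i + 5, Direction.DOWN, 0.001, Assay.ATAC)
            for i in range(n_down)
        ]
        return PeakTable(recs, Assay.ATAC)

    def test_study_scale_ratio(self):
        ratio, n_up, n_down = updown_ratio(self._table(908, 653), 0.001)
        assert ratio == 1.39
        assert (n_up, n_down) == (908, 653)

    def test_balanced_ratio(self):
        assert updown_ratio(self._table(5, 5), 0.05)[0] == 1.00

    def test_zero_down_rejected(self):
        with pytest.raises(ValidationError):
            updown_ratio(self._table(5, 0), 0.05)


class TestEnrichmentReport:
    def _setup(self):
        sizes = ChromSizes({"c1": 100_000})
        region = normalize([("c1", 80_000, 100_000)])
        recs = [
            PeakRecord("c1", 1_000 * i, 1_000 * i + 200, Direction.UP, 0.05, Assay.ATAC)
            for i in range(90)
        ]
        return sizes, region, PeakTable(recs, Assay.ATAC, label="q")

    def test_family_of_one_q_equals_p(self):
        sizes, region, table = self._setup()
        results = enrichment_report({"q": table}, {"r": region}, sizes)
        for r in results:
            assert r.q_value == pytest.approx(r.p_value)

    def test_q_matches_brute_force_bh_within_mode(self):
        sizes, region, table = self._setup()
        region2 = normalize([("c1", 0, 30_000)])
        table2 = PeakTable(
            [
                PeakRecord("c1", 50_000 + 300 * i, 50_000 + 300 * i + 100, Direction.DOWN, 0.05, Assay.ATAC)
                for i in range(40)
            ],
            Assay.ATAC,
            label="q2",
        )
        results = enrichment_report(
            {"q": table, "q2": table2}, {"r": region, "r2": region2}, sizes
        )
        for mode in ("bp", "peak"):
            fam = [r for r in results if r.mode == mode]
            assert len(fam) == 4
            expect = brute_force_bh([r.p_value for r in fam])
            for r, q in zip(fam, expect):
                assert r.q_value == pytest.approx(q)

    def test_both_modes_emitted_per_pair(self):
        sizes, region, table = self._setup()
        results = enrichment_report({"q": table}, {"r": region}, sizes)
        assert {r.mode for r in results} == {"bp", "peak"}


class TestPermutation:
    def test_region_covering_genome_gives_p_one(self):
        sizes = ChromSizes({"c1": 10_000})
        region = normalize([("c1", 0, 10_000)])
        table = PeakTable(
            [PeakRecord("c1", 100, 300, Direction.UP, 0.05, Assay.ATAC)], Assay.ATAC
        )
        assert permutation_enrichment(table, region, sizes, n_perm=49, seed=0) == 1.0

    def test_observed_below_null_gives_p_one(self):
        # peak placed entirely outside a large region: permutations beat it
        sizes = ChromSizes({"c1": 10_000})
        region = normalize([("c1", 1_000, 10_000)])
        table = PeakTable(
            [PeakRecord("c1", 0, 100, Direction.UP, 0.05, Assay.ATAC)], Assay.ATAC
        )
        p = permutation_enrichment(table, region, sizes, n_perm=199, seed=1)
        assert p > 0.9

    def test_peak_longer_than_chromosome_rejected(self):
        sizes = ChromSizes({"c1": 100})
        region = normalize([("c1", 0, 50)])
        table = PeakTable(
            [PeakRecord("c1", 0, 100, Direction.UP, 0.05, Assay.ATAC)], Assay.ATAC
        )
        bigger = ChromSizes({"c1": 50})
        with pytest.raises(ValidationError):
            permutation_enrichment(table, region, bigger, n_perm=9, seed=0)

    def test_invalid_n_perm(self):
        sizes = ChromSizes({"c1": 100})
        table = PeakTable(
            [PeakRecord("c1", 0, 10, Direction.UP, 0.05, Assay.ATAC)], Assay.ATAC
        )
        with pytest.raises(ValidationError):
            permutation_enrichment(table, normalize([("c1", 0, 50)]), sizes, n_perm=0)
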