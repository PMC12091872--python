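"""Enrichment statistics for peak sets against genomic region sets.

Two complementary tests per (query, region) pair:

* **bp mode** — a 2×2 base-pair contingency table (query∩region,
  query∖region, region∖query, remainder) analysed by Pearson's
  chi-squared (df=1, no continuity correction).  This is the headline
  number matching "% bp coverage" reporting, but note that bases within
  one peak are perfectly correlated, so its p-values are anticonservative;
  treat them as descriptive.
* **peak mode** — a goodness-of-fit chi-squared on the count of peaks
  overlapping the region versus the expectation under the region's
  genome fraction.  Peaks are (approximately) independent placements,
  so this test is the honest one for deciding enrichment.

A permutation test (peaks re-placed uniformly within their own
chromosome, lengths preserved) is provided as an assumption-free
alternative.  P-values within a report family are corrected with
Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .genome_model import ChromSizes
from .intervals import IntervalSet, count_overlapping
from .peakio import Direction, PeakTable

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "bp_contingency",
    "chi2_test",
    "bh_fdr",
    "updown_ratio",
    "enrichment_report",
    "permutation_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a=query∩region, b=query∖region, c=region∖query, d=remainder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    query: str
    region: str
    mode: str  # "bp" or "peak"
    observed_fraction: float
    background_fraction: float
    chi2_statistic: float
    p_value: float
    q_value: float = field(default=float("nan"))
    alpha: float = 0.05

    @property
    def enriched(self) -> bool:
        return (
            self.q_value < self.alpha
            and self.observed_fraction > self.background_fraction
        )


def bp_contingency(
    query: IntervalSet, region: IntervalSet, sizes: ChromSizes
) -> ContingencyTable2x2:
    """Base-pair 2×2 table; cells sum to the genome total."""
    if query.total_bp == 0:
        raise ValidationError("query interval set is empty")
    query.check_within(sizes)
    region.check_within(sizes)
    a = query.intersect(region).total_bp
    b = query.total_bp - a
    c = region.total_bp - a
    d = sizes.total_bp - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def chi2_test(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared on a 2×2 table, df=1, upper-tail p.

    Equivalent to N(ad−bc)² / (r₁r₂c₁c₂); zero marginals are rejected
    (use the permutation test for such degenerate geometries).
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError(
            "zero marginal in contingency table; use permutation_enrichment"
        )
    stat, p, _, _ = stats.chi2_contingency(
        np.array([[t.a, t.b], [t.c, t.d]]), correction=False
    )[:4]
    return float(stat), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def updown_ratio(peaks: PeakTable, tier: float) -> tuple[float, int, int]:
    """UP/DOWN peak-count ratio at a nested FDR tier.

    Returns (ratio rounded to 2 decimals, n_up, n_down).
    """
    n_up = peaks.count(Direction.UP, tier)
    n_down = peaks.count(Direction.DOWN, tier)
    if n_down == 0:
        raise ValidationError(f"no DOWN peaks at tier {tier}; ratio undefined")
    return (round(n_up / n_down, 2), n_up, n_down)


def _peak_mode_chi2(
    n_overlap: int, n_total: int, background: float
) -> tuple[float, float]:
    """Goodness-of-fit chi-squared of overlap count vs genome fraction."""
    expected = np.array([n_total * background, n_total * (1 - background)])
    if np.any(expected <= 0):
        raise ValidationError("degenerate background fraction for peak-mode test")
    observed = np.array([n_overlap, n_total - n_overlap])
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def enrichment_report(
    queries: dict[str, PeakTable],
    regions: dict[str, IntervalSet],
    sizes: ChromSizes,
    alpha: float = 0.05,
    min_bp: int = 1,
) -> list[EnrichmentResult]:
    """One EnrichmentResult per (query, region) pair and mode.

    BH correction is applied separately within the bp-mode family and
    the peak-mode family of this invocation; families are never pooled
    across calls.
    """
    results: list[EnrichmentResult] = []
    for mode in ("bp", "peak"):
        batch: list[EnrichmentResult] = []
        for qname, table in queries.items():
            if len(table) == 0:
                raise ValidationError(f"query {qname!r} has no peaks")
            qset = table.intervals()
            for rname, region in regions.items():
                background = region.total_bp / sizes.total_bp
                if mode == "bp":
                    t = bp_contingency(qset, region, sizes)
                    stat, p = chi2_test(t)
                    obs = t.a / (t.a + t.b)
                else:
                    raw = table.raw_intervals()
                    n_ov = count_overlapping(raw, region, min_bp=min_bp)
                    stat, p = _peak_mode_chi2(n_ov, len(raw), background)
                    obs = n_ov / len(raw)
                batch.append(
                    EnrichmentResult(
                        query=qname,
                        region=rname,
                        mode=mode,
                        observed_fraction=obs,
                        background_fraction=background,
                        chi2_statistic=stat,
                        p_value=p,
                        alpha=alpha,
                    )
                )
        qs = bh_fdr([r.p_value for r in batch])
        results.extend(
            EnrichmentResult(
                query=r.query,
                region=r.region,
                mode=r.mode,
                observed_fraction=r.observed_fraction,
                background_fraction=r.background_fraction,
                chi2_statistic=r.chi2_statistic,
                p_value=r.p_value,
                q_value=float(q),
                alpha=alpha,
            )
            for r, q in zip(batch, qs)
        )
    return results


def permutation_enrichment(
    query: PeakTable,
    region: IntervalSet,
    sizes: ChromSizes,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical enrichment p-value by uniform within-chromosome shuffles.

    Each peak is re-placed uniformly on its own chromosome with its
    length preserved (peaks may overlap after shuffling).  The statistic
    is the summed per-peak overlap (bp) with the region;
    p = (1 + #{permutation >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    observed = 0
    for rec in query:
        if rec.chrom not in sizes:
            raise ValidationError(f"peak chromosome {rec.chrom!r} not in ChromSizes")
        if rec.length > sizes[rec.chrom]:
            raise ValidationError(
                f"peak of {rec.length} bp exceeds chromosome {rec.chrom}"
            )
        by_chrom.setdefault(rec.chrom, []).append(rec.length)
        observed += int(
            region.overlap_bp(
                rec.chrom, np.asarray([rec.start]), np.asarray([rec.end])
            )[0]
        )
    perm_totals = np.zeros(n_perm, dtype=np.int64)
    for chrom, lengths in by_chrom.items():
        ln = np.asarray(lengths, dtype=np.int64)
        high = sizes[chrom] - ln + 1
        starts = (rng.random((n_perm, len(ln))) * high).astype(np.int64)
        flat_s = starts.ravel()
        flat_e = flat_s + np.tile(ln, n_perm)
        ov = region.overlap_bp(chrom, flat_s, flat_e).reshape(n_perm, len(ln))
        perm_totals += ov.sum(axis=1)
    return (1 + int(np.sum(perm_totals >= observed))) / (n_perm + 1)
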