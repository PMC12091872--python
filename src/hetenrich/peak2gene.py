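"""Peak-to-gene assignment: curated map first, nearest TSS otherwise.

A peak overlapping (>=1 bp) any curated regulatory region inherits the
union of that region's genes (source CURATED).  Peaks with no curated
hit are assigned the single gene whose TSS is nearest on the same
chromosome (source NEAREST); ties break to the lexicographically
smallest gene id.

Distance is edge-based and strand-agnostic: 0 when the TSS lies inside
the peak, otherwise the gap between the TSS and the nearest peak edge.
Peaks are classified proximal (<=5 kb) or distal, and binned 0-1 kb /
1-5 kb / >5 kb for the distance histograms.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .genome_model import CuratedRegionMap, GeneAnnotation
from .peakio import Direction, PeakRecord, PeakTable, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentSource",
    "DistanceBin",
    "GeneAssignment",
    "UNASSIGNED_GENE",
    "PROXIMAL_MAX_BP",
    "distance_to_tss",
    "bin_distance",
    "assign_peaks",
    "gene_sets_from_assignments",
    "write_assignments",
]

UNASSIGNED_GENE = "UNASSIGNED"
PROXIMAL_MAX_BP = 5000


class AssignmentSource(enum.Enum):
    CURATED = "CURATED"
    NEAREST = "NEAREST"
    UNASSIGNED = "UNASSIGNED"


class DistanceBin(enum.Enum):
    D0_1K = "0-1kb"
    D1_5K = "1-5kb"
    D5K_PLUS = ">5kb"


@dataclass(frozen=True)
class GeneAssignment:
    peak: PeakRecord
    genes: tuple[str, ...]
    source: AssignmentSource
    distance: int
    bin: DistanceBin

    @property
    def proximal(self) -> bool:
        return self.distance <= PROXIMAL_MAX_BP


def distance_to_tss(peak: PeakRecord, tss: int, chrom: str | None = None) -> int:
    """Edge distance between a peak and a TSS on the same chromosome.

    0 if the TSS falls inside the half-open peak span; otherwise the
    number of bases separating the TSS from the nearest peak edge.
    """
    if chrom is not None and chrom != peak.chrom:
        raise ValidationError(
            f"TSS chromosome {chrom!r} differs from peak chromosome {peak.chrom!r}"
        )
    if peak.start <= tss < peak.end:
        return 0
    if tss < peak.start:
        return peak.start - tss
    return tss - peak.end + 1


def bin_distance(d: int) -> DistanceBin:
    """Bin a TSS distance: [0,1000] / (1000,5000] / (5000,inf)."""
    if d < 0:
        raise ValidationError(f"negative distance {d}")
    if d <= 1000:
        return DistanceBin.D0_1K
    if d <= PROXIMAL_MAX_BP:
        return DistanceBin.D1_5K
    return DistanceBin.D5K_PLUS


def _nearest_gene(peak: PeakRecord, genes: GeneAnnotation) -> tuple[str, int] | None:
    tss, ids = genes.by_chrom(peak.chrom)
    if len(tss) == 0:
        return None
    d = np.where(
        tss < peak.start,
        peak.start - tss,
        np.where(tss >= peak.end, tss - peak.end + 1, 0),
    )
    dmin = int(d.min())
    tied = ids[d == dmin]
    return (min(tied), dmin)  # lexicographic tie-break


def assign_peaks(
    peaks: PeakTable,
    genes: GeneAnnotation,
    curated: CuratedRegionMap | None = None,
) -> list[GeneAssignment]:
    """Assign each peak to candidate gene(s).

    Curated regions take precedence at any overlap; the reported
    distance for a curated assignment is the minimum TSS distance over
    its genes (genes without a same-chromosome TSS contribute none; if
    no curated gene has one the region counts as directly annotated,
    distance 0).  Peaks on a chromosome with no genes and no curated
    hit get the UNASSIGNED sentinel.
    """
    out: list[GeneAssignment] = []
    n_unassigned = 0
    for peak in peaks:
        hit_genes: frozenset[str] = frozenset()
        if curated is not None:
            hit_genes = curated.overlapping_genes(peak.chrom, peak.start, peak.end)
        if hit_genes:
            dists = [
                distance_to_tss(peak, genes.tss_of(g)[1])
                for g in hit_genes
                if g in genes and genes.tss_of(g)[0] == peak.chrom
            ]
            dist = min(dists) if dists else 0
            out.append(
                GeneAssignment(
                    peak,
                    tuple(sorted(hit_genes)),
                    AssignmentSource.CURATED,
                    dist,
                    bin_distance(dist),
                )
            )
            continue
        nearest = _nearest_gene(peak, genes)
        if nearest is None:
            n_unassigned += 1
            out.append(
                GeneAssignment(
                    peak,
                    (UNASSIGNED_GENE,),
                    AssignmentSource.UNASSIGNED,
                    0,
                    DistanceBin.D0_1K,
                )
            )
            continue
        gene, dist = nearest
        out.append(
            GeneAssignment(
                peak, (gene,), AssignmentSource.NEAREST, dist, bin_distance(dist)
            )
        )
    if n_unassigned:
        logger.warning(
            "%d peak(s) on chromosomes without genes or curated hits left UNASSIGNED",
            n_unassigned,
        )
    return out


def gene_sets_from_assignments(
    assignments: list[GeneAssignment],
    direction: Direction,
    name: str | None = None,
) -> GeneSet:
    """Unique candidate genes over peaks of one direction."""
    genes: set[str] = set()
    for a in assignments:
        if a.peak.direction is direction:
            genes.update(g for g in a.genes if g != UNASSIGNED_GENE)
    return GeneSet(name or f"assigned-{direction.value}", direction.value, frozenset(genes))


def write_assignments(assignments: list[GeneAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpeak_id\tdirection\tfdr_tier\tgenes\tsource\tdistance\tbin\tproximal\n"
        )
        for a in assignments:
            p = a.peak
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id or '.'}\t"
                f"{p.direction.value}\t{p.fdr_tier}\t{';'.join(a.genes)}\t"
                f"{a.source.value}\t{a.distance}\t{a.bin.value}\t{int(a.proximal)}\n"
            )
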