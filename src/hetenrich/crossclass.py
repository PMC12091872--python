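"""Cross-classification of peaks and gene sets.

Produces the figure-panel style breakdowns: TSS-distance histograms per
direction, expressed/not-expressed splits of candidate gene sets,
five-colour chromatin-state composition of peak sets (with the gray
UNASSIGNED sector), and pairwise gene-set overlaps (Venn counts with
percentages relative to each set).

Every breakdown carries its raw counts and denominator alongside the
percentages, so no reported fraction has an implicit denominator.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Callable, Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_model import ChromatinStateMap, STATE_PRIORITY, UNASSIGNED
from .peak2gene import GeneAssignment, UNASSIGNED_GENE, DistanceBin
from .peakio import Direction, GeneSet, PeakTable

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSubset",
    "BreakdownTable",
    "expression_breakdown",
    "state_breakdown",
    "distance_histogram",
    "venn",
    "peak_states",
]


class ExpressionSubset(enum.Enum):
    TOTAL = "TOTAL"
    EXPRESSED = "EXPRESSED"
    NOT_EXPRESSED = "NOT_EXPRESSED"


@dataclass(frozen=True)
class BreakdownTable:
    """Stratum counts with percentages over an explicit denominator."""

    title: str
    labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.counts):
            raise ValidationError("labels/counts length mismatch")
        if self.denominator == 0:
            raise ValidationError(f"breakdown {self.title!r} has empty denominator")

    @property
    def denominator(self) -> int:
        return int(sum(self.counts))

    @property
    def percentages(self) -> tuple[float, ...]:
        d = self.denominator
        return tuple(100.0 * c / d for c in self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.labels,
                "count": self.counts,
                "percentage": [round(p, 1) for p in self.percentages],
                "denominator": self.denominator,
            }
        )


def expression_breakdown(
    gs: GeneSet, expressed: Callable[[str], bool], title: str | None = None
) -> BreakdownTable:
    """Split a gene set into expressed / not-expressed counts.

    Genes the predicate cannot decide (raises KeyError) are counted
    NOT_EXPRESSED with a warning, mirroring absence from a wild-type
    expression catalogue.
    """
    if len(gs) == 0:
        raise ValidationError(f"gene set {gs.name!r} is empty; no denominator")
    n_exp = n_not = n_unknown = 0
    for g in sorted(gs.genes):
        try:
            is_exp = bool(expressed(g))
        except KeyError:
            n_unknown += 1
            is_exp = False
        if is_exp:
            n_exp += 1
        else:
            n_not += 1
    if n_unknown:
        logger.warning(
            "%s: %d gene(s) missing from expression predicate; counted NOT_EXPRESSED",
            gs.name,
            n_unknown,
        )
    return BreakdownTable(
        title or f"expression:{gs.name}",
        ("EXPRESSED", "NOT_EXPRESSED"),
        (n_exp, n_not),
    )


def peak_states(
    peaks: Iterable, states: ChromatinStateMap
) -> list[str]:
    """Assign each peak the chromatin colour covering most of its bases.

    Zero overlap with every state → UNASSIGNED.  Coverage ties break by
    the fixed colour priority BLACK>BLUE>GREEN>YELLOW>RED.
    """
    out = []
    for peak in peaks:
        best_state, best_cov = UNASSIGNED, 0
        for state in STATE_PRIORITY:
            cov = int(
                states.state_sets[state].overlap_bp(
                    peak.chrom, np.asarray([peak.start]), np.asarray([peak.end])
                )[0]
            )
            if cov > best_cov:
                best_state, best_cov = state.value, cov
        out.append(best_state)
    return out


def _assignment_expressed(
    assignment: GeneAssignment, expressed: Callable[[str], bool]
) -> bool:
    """A peak counts as expressed when any assigned gene is expressed."""
    for g in assignment.genes:
        if g == UNASSIGNED_GENE:
            continue
        try:
            if expressed(g):
                return True
        except KeyError:
            continue
    return False


def state_breakdown(
    peaks: PeakTable,
    states: ChromatinStateMap,
    subset: ExpressionSubset = ExpressionSubset.TOTAL,
    assignments: list[GeneAssignment] | None = None,
    expressed: Callable[[str], bool] | None = None,
    title: str | None = None,
) -> BreakdownTable:
    """Chromatin-colour composition of a peak set.

    For the EXPRESSED / NOT_EXPRESSED subsets, peaks are filtered by
    the expression status of their assigned gene(s); *assignments* and
    *expressed* are then required.
    """
    records = list(peaks)
    if subset is not ExpressionSubset.TOTAL:
        if assignments is None or expressed is None:
            raise ValidationError(
                "EXPRESSED/NOT_EXPRESSED subsets need assignments and a predicate"
            )
        by_peak = {a.peak: a for a in assignments}
        keep = []
        for rec in records:
            a = by_peak.get(rec)
            if a is None:
                raise ValidationError("assignments do not cover the peak table")
            is_exp = _assignment_expressed(a, expressed)
            if (subset is ExpressionSubset.EXPRESSED) == is_exp:
                keep.append(rec)
        records = keep
    if not records:
        raise ValidationError(f"no peaks in subset {subset.value}; no denominator")
    labels = [s.value for s in STATE_PRIORITY] + [UNASSIGNED]
    assigned = peak_states(records, states)
    counts = [sum(1 for a in assigned if a == lab) for lab in labels]
    return BreakdownTable(
        title or f"states:{peaks.label}:{subset.value}", tuple(labels), tuple(counts)
    )


def distance_histogram(
    assignments: list[GeneAssignment],
    direction: Direction,
    title: str | None = None,
) -> BreakdownTable:
    """TSS-distance bin percentages for peaks of one direction."""
    bins = [a.bin for a in assignments if a.peak.direction is direction]
    if not bins:
        raise ValidationError(f"no peaks of direction {direction.value}")
    labels = tuple(b.value for b in DistanceBin)
    counts = tuple(sum(1 for b in bins if b is db) for db in DistanceBin)
    return BreakdownTable(title or f"distance:{direction.value}", labels, counts)


def venn(a: GeneSet, b: GeneSet) -> dict:
    """Pairwise overlap of two gene sets with per-set percentages."""
    both = a.genes & b.genes
    return {
        "only_a": len(a.genes - b.genes),
        "only_b": len(b.genes - a.genes),
        "both": len(both),
        "pct_of_a": 100.0 * len(both) / len(a.genes) if a.genes else 0.0,
        "pct_of_b": 100.0 * len(both) / len(b.genes) if b.genes else 0.0,
    }
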