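"""Differential peak tables and differential-expression gene sets.

Peak tables are BED-like inputs from an upstream differential-binding
caller: each record carries a direction (UP = more accessible/enriched
in the perturbed condition, DOWN = less) and the FDR tier at which it
was called (0.05, 0.01 or 0.001; tiers are nested, so a 0.001 peak also
counts at the looser tiers).  Gene tables carry per-gene log2
fold-change and a significance value; set-defining thresholds are
strict inequalities.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError
from .genome_model import ChromSizes
from .intervals import IntervalSet, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "Assay",
    "FDR_TIERS",
    "PeakRecord",
    "PeakTable",
    "GeneSetFilterSpec",
    "GeneSet",
    "read_peaks",
    "write_peaks",
    "filter_gene_table",
]

FDR_TIERS = (0.05, 0.01, 0.001)


class Direction(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"


class Assay(enum.Enum):
    ATAC = "ATAC"
    H3K27AC = "H3K27ac"


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    direction: Direction
    fdr_tier: float
    assay: Assay
    log2fc: float | None = None
    peak_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end or self.start < 0:
            raise ValidationError(
                f"bad peak interval ({self.chrom},{self.start},{self.end})"
            )
        if self.fdr_tier not in FDR_TIERS:
            raise ValidationError(
                f"fdr_tier {self.fdr_tier} not in {FDR_TIERS}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakTable:
    """A validated list of same-assay differential peaks."""

    def __init__(
        self,
        records: Iterable[PeakRecord],
        assay: Assay,
        label: str = "",
        genotype: str = "",
        sizes: ChromSizes | None = None,
    ):
        self.records: tuple[PeakRecord, ...] = tuple(records)
        self.assay = assay
        self.label = label or assay.value
        self.genotype = genotype
        for rec in self.records:
            if rec.assay is not assay:
                raise ValidationError(
                    f"peak {rec} has assay {rec.assay}, table declares {assay}"
                )
            if sizes is not None:
                if rec.chrom not in sizes:
                    raise ValidationError(
                        f"peak on unknown chromosome {rec.chrom!r}"
                    )
                if rec.end > sizes[rec.chrom]:
                    raise ValidationError(
                        f"peak ({rec.chrom},{rec.start},{rec.end}) beyond chromosome end"
                    )
        coords_by_dir: dict[tuple, set] = {}
        for rec in self.records:
            coords_by_dir.setdefault((rec.chrom, rec.start, rec.end), set()).add(
                rec.direction
            )
        both = [k for k, v in coords_by_dir.items() if len(v) > 1]
        if both:
            raise ValidationError(
                f"peak(s) {both[:3]} appear in both UP and DOWN strata"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(
        self,
        direction: Direction | None = None,
        tier: float | None = None,
        label: str | None = None,
    ) -> "PeakTable":
        """Filter by direction and/or nested FDR tier (tier<=t kept)."""
        recs = [
            r
            for r in self.records
            if (direction is None or r.direction is direction)
            and (tier is None or r.fdr_tier <= tier + 1e-12)
        ]
        return PeakTable(recs, self.assay, label or self.label, self.genotype)

    def count(self, direction: Direction, tier: float) -> int:
        """Peaks of *direction* at or below the nested tier."""
        return len(self.subset(direction=direction, tier=tier))

    def intervals(self) -> IntervalSet:
        """Merged interval footprint of all records."""
        return normalize((r.chrom, r.start, r.end) for r in self.records)

    def raw_intervals(self) -> list[tuple[str, int, int]]:
        return [(r.chrom, r.start, r.end) for r in self.records]


# -- reading / writing -------------------------------------------------

_BED6_MIN_COLS = 8  # chrom start end name score strand direction tier


def _parse_direction(token: str, where: str) -> Direction:
    try:
        return Direction(token.upper())
    except ValueError as exc:
        raise ValidationError(f"{where}: bad direction token {token!r}") from exc


def _parse_tier(token: str, where: str) -> float:
    try:
        tier = float(token)
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric FDR tier {token!r}") from exc
    for t in FDR_TIERS:
        if abs(tier - t) < 1e-9:
            return t
    raise ValidationError(f"{where}: unknown FDR tier {token!r} (expected one of {FDR_TIERS})")


def read_peaks(
    path: str | Path,
    assay: Assay,
    dialect: str = "bed6plus",
    sizes: ChromSizes | None = None,
    label: str = "",
    merge_overlaps: bool = True,
) -> PeakTable:
    """Read a differential peak table.

    ``bed6plus``: cols 1-3 coordinates, col 4 id, col 5 score, col 6
    ".", col 7 direction, col 8 FDR tier (optional col 9 log2FC).
    ``tsv``: headered table with columns chrom/start/end/direction/
    fdr_tier and optional log2fc/id.

    Overlapping records within one (direction, tier) stratum are merged
    with a logged warning — duplicated calls within a stratum would
    otherwise double-count bases.
    """
    records: list[PeakRecord] = []
    if dialect in ("bed6plus", "bed"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < _BED6_MIN_COLS:
                    raise ParseError(
                        f"{path}:{ln}: expected >= {_BED6_MIN_COLS} columns"
                    )
                where = f"{path}:{ln}"
                records.append(
                    PeakRecord(
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        peak_id=f[3] or None,
                        direction=_parse_direction(f[6], where),
                        fdr_tier=_parse_tier(f[7], where),
                        assay=assay,
                        log2fc=float(f[8]) if len(f) > 8 and f[8] not in ("", ".") else None,
                    )
                )
    elif dialect in ("tsv", "tsv-headered"):
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end", "direction", "fdr_tier"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in df.iterrows():
            where = f"{path}:row {i}"
            records.append(
                PeakRecord(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    direction=_parse_direction(str(row["direction"]), where),
                    fdr_tier=_parse_tier(str(row["fdr_tier"]), where),
                    assay=assay,
                    log2fc=float(row["log2fc"]) if "log2fc" in df.columns and pd.notna(row["log2fc"]) else None,
                    peak_id=str(row["id"]) if "id" in df.columns and pd.notna(row["id"]) else None,
                )
            )
    else:
        raise ValidationError(f"unknown peak dialect {dialect!r}")
    if merge_overlaps:
        records = _merge_stratum_overlaps(records, str(path))
    return PeakTable(records, assay, label=label, sizes=sizes)


def _merge_stratum_overlaps(
    records: list[PeakRecord], source: str
) -> list[PeakRecord]:
    """Merge overlapping peaks within each (direction, tier) stratum."""
    by_stratum: dict[tuple, list[PeakRecord]] = {}
    for rec in records:
        by_stratum.setdefault((rec.direction, rec.fdr_tier, rec.chrom), []).append(rec)
    out: list[PeakRecord] = []
    n_merged = 0
    for recs in by_stratum.values():
        recs.sort(key=lambda r: r.start)
        cur = recs[0]
        for rec in recs[1:]:
            if rec.start < cur.end:  # strict overlap; adjacency kept distinct
                n_merged += 1
                ids = [i for i in (cur.peak_id, rec.peak_id) if i]
                cur = replace(
                    cur,
                    end=max(cur.end, rec.end),
                    peak_id=";".join(ids) or None,
                    log2fc=None if cur.log2fc != rec.log2fc else cur.log2fc,
                )
            else:
                out.append(cur)
                cur = rec
        out.append(cur)
    if n_merged:
        logger.warning(
            "%s: merged %d overlapping record(s) within (direction, tier) strata",
            source,
            n_merged,
        )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def write_peaks(table: PeakTable, path: str | Path) -> None:
    """Write the BED6+ dialect read_peaks accepts."""
    with open(path, "w") as fh:
        for i, r in enumerate(table.records):
            pid = r.peak_id or f"{table.label}_{i}"
            fc = "." if r.log2fc is None else f"{r.log2fc:.4f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{pid}\t0\t.\t"
                f"{r.direction.value}\t{r.fdr_tier}\t{fc}\n"
            )


# -- gene sets ---------------------------------------------------------


@dataclass(frozen=True)
class GeneSetFilterSpec:
    """Thresholds defining differential gene sets (strict inequalities)."""

    log2fc_threshold: float
    significance_threshold: float
    significance_kind: str = "FDR"  # or "P"

    def __post_init__(self):
        if self.log2fc_threshold <= 0:
            raise ValidationError("log2fc_threshold must be > 0")
        if not 0 < self.significance_threshold < 1:
            raise ValidationError("significance_threshold must be in (0,1)")
        if self.significance_kind not in ("FDR", "P"):
            raise ValidationError("significance_kind must be 'FDR' or 'P'")


@dataclass(frozen=True)
class GeneSet:
    name: str
    direction: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def filter_gene_table(
    rows: pd.DataFrame, spec: GeneSetFilterSpec, name: str = "genes"
) -> tuple[GeneSet, GeneSet]:
    """Split a differential-expression table into UP and DOWN gene sets.

    *rows* needs columns ``gene_id``, ``log2fc`` and ``significance``
    (the p-value or FDR named by ``spec.significance_kind``).  Membership
    uses strict inequalities: up = log2fc > t and sig < cutoff; down =
    log2fc < −t and sig < cutoff.  Boundary-equal values are excluded.
    """
    required = {"gene_id", "log2fc", "significance"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"gene table missing columns {sorted(missing)}")
    if rows["gene_id"].duplicated().any():
        dups = rows.loc[rows["gene_id"].duplicated(), "gene_id"].tolist()[:3]
        raise ValidationError(f"duplicate gene rows: {dups}")
    sig_ok = rows["significance"] < spec.significance_threshold
    up = frozenset(rows.loc[sig_ok & (rows["log2fc"] > spec.log2fc_threshold), "gene_id"])
    down = frozenset(rows.loc[sig_ok & (rows["log2fc"] < -spec.log2fc_threshold), "gene_id"])
    return (
        GeneSet(f"{name}-UP", "UP", up),
        GeneSet(f"{name}-DOWN", "DOWN", down),
    )
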