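"""Genome representation and annotation loading.

Covers the static context of the analysis: chromosome sizes, the
pericentromeric heterochromatin map built from per-arm epigenetic
boundary coordinates, gene annotations (TSS positions), curated
regulatory-region→gene maps, and the five-colour chromatin-state
segmentation (black/blue/green repressive, yellow/red active).

Coordinates are 0-based half-open internally; 1-based inclusive file
dialects (GFF) are converted at the I/O boundary.  Chromosomes absent
from :class:`ChromSizes` (e.g. the Y chromosome in a mixed-sex design)
are excluded from every denominator.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError
from .intervals import IntervalSet, normalize

__all__ = [
    "ChromSizes",
    "Side",
    "ArmBoundary",
    "BoundarySpec",
    "PericentromericMap",
    "GeneRecord",
    "GeneAnnotation",
    "CuratedRegionMap",
    "ChromatinState",
    "ChromatinStateMap",
    "UNASSIGNED",
    "load_chrom_sizes",
    "write_chrom_sizes",
    "build_pericentromeric_map",
    "load_genes",
    "write_genes",
    "load_states",
    "write_states",
    "load_curated",
    "write_curated",
]

UNASSIGNED = "UNASSIGNED"


class ChromSizes(Mapping[str, int]):
    """Chromosome-name → length (bp) map; the genome denominator."""

    def __init__(self, entries: Mapping[str, int]):
        self._entries: dict[str, int] = {}
        for name, length in entries.items():
            if name in self._entries:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")
            self._entries[name] = length
        if not self._entries:
            raise ValidationError("ChromSizes must contain at least one chromosome")

    def __getitem__(self, name: str) -> int:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def total_bp(self) -> int:
        return sum(self._entries.values())

    def __repr__(self) -> str:
        return f"ChromSizes({len(self)} chromosomes, {self.total_bp} bp)"


class Side(enum.Enum):
    """Which side of an arm boundary is heterochromatic."""

    LEFT_OF_BOUNDARY = "LEFT_OF_BOUNDARY"
    RIGHT_OF_BOUNDARY = "RIGHT_OF_BOUNDARY"


@dataclass(frozen=True)
class ArmBoundary:
    chrom: str
    boundary: int
    side: Side


@dataclass(frozen=True)
class BoundarySpec:
    """Per-arm heterochromatin boundaries plus whole-chromosome flags.

    Boundary coordinates are epigenetic euchromatin/heterochromatin
    transitions (e.g. abrupt H3K9me2 drops); chromosomes listed in
    ``whole_chromosomes`` (classically the small fourth chromosome) are
    treated as heterochromatic along their entire length.
    """

    arms: tuple[ArmBoundary, ...] = ()
    whole_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self):
        seen = set()
        for arm in self.arms:
            key = (arm.chrom, arm.side)
            if key in seen:
                raise ValidationError(
                    f"arm ({arm.chrom}, {arm.side.value}) specified twice"
                )
            seen.add(key)
            if arm.chrom in self.whole_chromosomes:
                raise ValidationError(
                    f"{arm.chrom!r} is flagged whole-chromosome and also has a boundary"
                )


@dataclass(frozen=True)
class PericentromericMap:
    """Heterochromatic territory with its genome-wide fraction (f_het)."""

    intervals: IntervalSet
    genome_fraction: float

    @property
    def total_bp(self) -> int:
        return self.intervals.total_bp


def build_pericentromeric_map(
    spec: BoundarySpec, sizes: ChromSizes
) -> PericentromericMap:
    """Turn per-arm boundary coordinates into a pericentromeric interval map.

    LEFT_OF_BOUNDARY arms contribute ``[0, boundary)``; RIGHT_OF_BOUNDARY
    arms contribute ``[boundary, length)``; flagged chromosomes contribute
    their full length.  The genome fraction uses all chromosomes in
    *sizes* as the denominator.
    """
    records: list[tuple[str, int, int]] = []
    for arm in spec.arms:
        if arm.chrom not in sizes:
            raise ValidationError(f"boundary references unknown chromosome {arm.chrom!r}")
        length = sizes[arm.chrom]
        if not 0 <= arm.boundary <= length:
            raise ValidationError(
                f"boundary {arm.boundary} outside [0,{length}] on {arm.chrom}"
            )
        if arm.side is Side.LEFT_OF_BOUNDARY:
            if arm.boundary > 0:
                records.append((arm.chrom, 0, arm.boundary))
        else:
            if arm.boundary < length:
                records.append((arm.chrom, arm.boundary, length))
    for chrom in spec.whole_chromosomes:
        if chrom not in sizes:
            raise ValidationError(f"flagged chromosome {chrom!r} not in ChromSizes")
        records.append((chrom, 0, sizes[chrom]))
    iset = normalize(records)
    return PericentromericMap(iset, iset.total_bp / sizes.total_bp)


# -- gene annotation ---------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based


class GeneAnnotation:
    """TSS-indexed gene annotation with fast per-chromosome lookup."""

    def __init__(self, records: Iterable[GeneRecord], sizes: ChromSizes | None = None):
        self.records: tuple[GeneRecord, ...] = tuple(records)
        seen: set[str] = set()
        by_chrom: dict[str, list[GeneRecord]] = {}
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            if rec.strand not in ("+", "-"):
                raise ValidationError(
                    f"gene {rec.gene_id!r}: unknown strand {rec.strand!r}"
                )
            if rec.tss < 0:
                raise ValidationError(f"gene {rec.gene_id!r}: negative TSS")
            if sizes is not None:
                if rec.chrom not in sizes:
                    raise ValidationError(
                        f"gene {rec.gene_id!r} on unknown chromosome {rec.chrom!r}"
                    )
                if rec.tss >= sizes[rec.chrom]:
                    raise ValidationError(
                        f"gene {rec.gene_id!r}: TSS beyond chromosome end"
                    )
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.tss, r.gene_id))
            self._by_chrom[chrom] = (
                np.asarray([r.tss for r in recs], dtype=np.int64),
                np.asarray([r.gene_id for r in recs], dtype=object),
            )
        self._tss_of = {r.gene_id: (r.chrom, r.tss) for r in self.records}

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(tss positions sorted, gene ids) for one chromosome."""
        return self._by_chrom.get(
            chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=object))
        )

    def tss_of(self, gene_id: str) -> tuple[str, int]:
        return self._tss_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._tss_of

    def __len__(self) -> int:
        return len(self.records)


# -- curated region→gene map ------------------------------------------


class CuratedRegionMap:
    """ORegAnno-style curated regulatory regions mapped to gene sets.

    Regions may overlap each other; each carries at least one gene id.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, int, int, frozenset[str]]],
        sizes: ChromSizes | None = None,
    ):
        self.records: list[tuple[str, int, int, frozenset[str]]] = []
        by_chrom: dict[str, list[tuple[int, int, frozenset[str]]]] = {}
        for chrom, start, end, genes in records:
            genes = frozenset(genes)
            if not genes:
                raise ValidationError(f"curated region ({chrom},{start},{end}) has no genes")
            if start >= end or start < 0:
                raise ValidationError(f"bad curated interval ({chrom},{start},{end})")
            if sizes is not None:
                if chrom not in sizes or end > sizes[chrom]:
                    raise ValidationError(
                        f"curated region ({chrom},{start},{end}) outside genome"
                    )
            self.records.append((chrom, start, end, genes))
            by_chrom.setdefault(chrom, []).append((start, end, genes))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[frozenset[str]]]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r[0])
            self._by_chrom[chrom] = (
                np.asarray([r[0] for r in recs], dtype=np.int64),
                np.asarray([r[1] for r in recs], dtype=np.int64),
                [r[2] for r in recs],
            )

    def overlapping_genes(self, chrom: str, start: int, end: int) -> frozenset[str]:
        """Union of gene sets of every curated region overlapping >=1 bp."""
        if chrom not in self._by_chrom:
            return frozenset()
        starts, ends, genes = self._by_chrom[chrom]
        hit = (starts < end) & (ends > start)
        out: set[str] = set()
        for i in np.flatnonzero(hit):
            out |= genes[i]
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.records)


# -- chromatin states --------------------------------------------------


class ChromatinState(enum.Enum):
    BLACK = "BLACK"
    BLUE = "BLUE"
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


# tie-break priority for peak→state assignment (repressive states first)
STATE_PRIORITY = (
    ChromatinState.BLACK,
    ChromatinState.BLUE,
    ChromatinState.GREEN,
    ChromatinState.YELLOW,
    ChromatinState.RED,
)


class ChromatinStateMap:
    """Five-colour chromatin segmentation; non-overlapping segments.

    Positions not covered by any segment are UNASSIGNED (reported as the
    gray sector in breakdowns).
    """

    def __init__(
        self,
        segments: Iterable[tuple[str, int, int, ChromatinState]],
        sizes: ChromSizes | None = None,
    ):
        self.segments: list[tuple[str, int, int, ChromatinState]] = []
        per_state: dict[ChromatinState, list[tuple[str, int, int]]] = {
            s: [] for s in ChromatinState
        }
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, state in segments:
            if start >= end or start < 0:
                raise ValidationError(f"bad state segment ({chrom},{start},{end})")
            if sizes is not None and (chrom not in sizes or end > sizes[chrom]):
                raise ValidationError(f"state segment ({chrom},{start},{end}) outside genome")
            self.segments.append((chrom, start, end, state))
            per_state[state].append((chrom, start, end))
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping state segments on {chrom} near {s2}"
                    )
        self.state_sets: dict[ChromatinState, IntervalSet] = {
            s: normalize(per_state[s]) for s in ChromatinState
        }

    def state_bp(self, state: ChromatinState) -> int:
        return self.state_sets[state].total_bp

    @property
    def assigned_bp(self) -> int:
        return sum(self.state_bp(s) for s in ChromatinState)

    def __len__(self) -> int:
        return len(self.segments)


# -- file I/O ----------------------------------------------------------


def load_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column name/length table."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{ln}: expected 2 tab-separated columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer length {fields[1]!r}") from exc
            if name in entries:
                raise ValidationError(f"{path}:{ln}: duplicate chromosome {name!r}")
            entries[name] = length
    if not entries:
        raise ValidationError(f"{path}: no chromosomes found")
    return ChromSizes(entries)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sizes:
            fh.write(f"{name}\t{sizes[name]}\n")


def load_genes(
    path: str | Path,
    dialect: str = "refflat",
    sizes: ChromSizes | None = None,
) -> GeneAnnotation:
    """Read gene annotations and derive 0-based TSS coordinates.

    ``refflat`` dialect: tab-separated with 0-based half-open tx spans —
    either the simplified 5-column layout (gene, chrom, strand, start,
    end) or full 11-column refFlat (geneName, name, chrom, strand,
    txStart, txEnd, ...).  ``gff`` dialect: GFF3 ``gene`` features,
    1-based inclusive, converted on read.  TSS = span start on '+',
    span end − 1 on '-' (0-based).
    """
    records: list[GeneRecord] = []
    if dialect in ("refflat", "refflat-like"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) >= 11:  # full refFlat
                    gene, chrom, strand, start, end = f[0], f[2], f[3], f[4], f[5]
                elif len(f) >= 5:
                    gene, chrom, strand, start, end = f[0], f[1], f[2], f[3], f[4]
                else:
                    raise ParseError(f"{path}:{ln}: expected >=5 columns")
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: non-integer span") from exc
                records.append(_gene_record(gene, chrom, strand, start_i, end_i, ln, path))
    elif dialect in ("gff", "gff-like", "gff3"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ParseError(f"{path}:{ln}: expected 9 GFF columns")
                if f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene = attrs.get("ID") or attrs.get("gene_id")
                if not gene:
                    raise ParseError(f"{path}:{ln}: gene feature lacks ID attribute")
                # 1-based inclusive -> 0-based half-open
                start_i, end_i = int(f[3]) - 1, int(f[4])
                records.append(_gene_record(gene, f[0], f[6], start_i, end_i, ln, path))
    else:
        raise ValidationError(f"unknown gene dialect {dialect!r}")
    return GeneAnnotation(records, sizes=sizes)


def _gene_record(
    gene: str, chrom: str, strand: str, start: int, end: int, ln: int, path
) -> GeneRecord:
    if strand not in ("+", "-"):
        raise ValidationError(f"{path}:{ln}: unknown strand symbol {strand!r}")
    if start >= end:
        raise ValidationError(f"{path}:{ln}: empty gene span")
    tss = start if strand == "+" else end - 1
    return GeneRecord(gene, chrom, strand, tss)


def write_genes(
    annotation: GeneAnnotation, path: str | Path, spans: Mapping[str, tuple[int, int]] | None = None
) -> None:
    """Write simplified 5-column refFlat-style annotation (0-based half-open).

    *spans* optionally supplies (start, end) per gene; by default a
    1 bp span anchored at the TSS is written, which round-trips the TSS
    exactly for both strands.
    """
    with open(path, "w") as fh:
        for rec in annotation.records:
            if spans and rec.gene_id in spans:
                start, end = spans[rec.gene_id]
            else:
                start, end = rec.tss, rec.tss + 1
            fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.strand}\t{start}\t{end}\n")


def load_states(path: str | Path, sizes: ChromSizes | None = None) -> ChromatinStateMap:
    """Read a BED4 file whose 4th column is a chromatin colour name."""
    segments = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 BED columns")
            try:
                state = ChromatinState(f[3].upper())
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: unknown state name {f[3]!r}") from exc
            segments.append((f[0], int(f[1]), int(f[2]), state))
    return ChromatinStateMap(segments, sizes=sizes)


def write_states(states: ChromatinStateMap, path: str | Path) -> None:
    segs = sorted(states.segments, key=lambda s: (s[0], s[1]))
    with open(path, "w") as fh:
        for chrom, start, end, state in segs:
            fh.write(f"{chrom}\t{start}\t{end}\t{state.value}\n")


def load_curated(path: str | Path, sizes: ChromSizes | None = None) -> CuratedRegionMap:
    """Read a BED4 file whose 4th column is a semicolon-joined gene list."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 BED columns")
            genes = frozenset(g for g in f[3].split(";") if g)
            if not genes:
                raise ValidationError(f"{path}:{ln}: empty gene list")
            records.append((f[0], int(f[1]), int(f[2]), genes))
    return CuratedRegionMap(records, sizes=sizes)


def write_curated(curated: CuratedRegionMap, path: str | Path) -> None:
    recs = sorted(curated.records, key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, genes in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{';'.join(sorted(genes))}\n")
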