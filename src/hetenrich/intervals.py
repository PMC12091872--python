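"""Genomic interval-set arithmetic on half-open, 0-based coordinates.

An :class:`IntervalSet` holds, per chromosome, a sorted array of pairwise
disjoint ``[start, end)`` intervals.  It is the unit of every base-pair
overlap computation in the package: pericentromeric maps, ChIP-domain
tracks and peak sets are all reduced to interval sets before coverage or
enrichment is measured.

All public constructors normalize their input: intervals are sorted,
overlapping or touching intervals are merged (half-open semantics, so
``[0,100)`` and ``[100,200)`` merge into ``[0,200)``).  This makes the
coverage identities exact, e.g. ``bp(A∪B) = bp(A) + bp(B) − bp(A∩B)``.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "IntervalSet",
    "normalize",
    "intersect",
    "union",
    "subtract",
    "coverage_fraction",
    "count_overlapping",
    "read_bed3",
    "write_bed3",
]

Record = tuple[str, int, int]


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge a (n,2) array sorted by start into disjoint intervals."""
    if len(arr) <= 1:
        return arr
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or adjacency merges
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """Normalized per-chromosome disjoint half-open intervals."""

    __slots__ = ("_data", "_cum")

    def __init__(self, data: dict[str, np.ndarray], *, _normalized: bool = False):
        norm: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                continue
            if np.any(arr[:, 0] < 0):
                raise ValidationError(f"negative coordinate on {chrom}")
            bad = arr[:, 0] >= arr[:, 1]
            if np.any(bad):
                s, e = arr[bad][0]
                raise ValidationError(f"empty/inverted interval ({chrom},{s},{e})")
            if not _normalized:
                arr = _merge_sorted(arr[np.argsort(arr[:, 0], kind="stable")])
            norm[chrom] = arr
        self._data = norm
        # per-chrom prefix coverage, for O(log n) bp-in-[0,x) queries
        self._cum = {
            c: np.concatenate(([0], np.cumsum(a[:, 1] - a[:, 0])))
            for c, a in norm.items()
        }

    @classmethod
    def from_records(cls, records: Iterable[Record]) -> "IntervalSet":
        data: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            data.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in data.items()})

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls({})

    # -- basic queries -------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._data))

    def per_chrom(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def records(self) -> Iterator[Record]:
        for chrom in self.chroms:
            for s, e in self._data[chrom]:
                yield (chrom, int(s), int(e))

    @property
    def total_bp(self) -> int:
        return int(sum(self._cum[c][-1] for c in self._data))

    def bp_on(self, chrom: str) -> int:
        return int(self._cum[chrom][-1]) if chrom in self._cum else 0

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.chroms == other.chroms and all(
            np.array_equal(self._data[c], other._data[c]) for c in self._data
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    # -- coverage queries ----------------------------------------------

    def _coverage_before(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Covered bp in [0, x) for a vector of positions on one chromosome."""
        if chrom not in self._data:
            return np.zeros_like(x, dtype=np.int64)
        arr = self._data[chrom]
        cum = self._cum[chrom]
        i = np.searchsorted(arr[:, 0], x, side="right")
        base = cum[np.maximum(i - 1, 0)] * (i > 0)
        prev_s = arr[np.maximum(i - 1, 0), 0]
        prev_e = arr[np.maximum(i - 1, 0), 1]
        partial = np.clip(x - prev_s, 0, prev_e - prev_s) * (i > 0)
        return base + partial

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vector of intersecting bp for query intervals on one chromosome."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._coverage_before(chrom, ends) - self._coverage_before(chrom, starts)

    # -- set algebra ---------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in self._data:
            if chrom not in other._data:
                continue
            a, b = self._data[chrom], other._data[chrom]
            pieces = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    pieces.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet(out, _normalized=True)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._data) | set(other._data):
            out[chrom] = np.concatenate(
                [self.per_chrom(chrom), other.per_chrom(chrom)]
            )
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._data.items():
            b = other.per_chrom(chrom)
            if len(b) == 0:
                out[chrom] = a
                continue
            pieces = []
            j = 0
            for s, e in a:
                cur = int(s)
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        pieces.append((cur, int(b[k, 0])))
                    cur = max(cur, int(b[k, 1]))
                    k += 1
                if cur < e:
                    pieces.append((cur, int(e)))
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet(out, _normalized=True)

    def check_within(self, sizes) -> None:
        """Raise unless every interval fits its chromosome in *sizes*."""
        for chrom, arr in self._data.items():
            if chrom not in sizes:
                raise ValidationError(f"chromosome {chrom!r} absent from ChromSizes")
            if len(arr) and int(arr[-1, 1]) > sizes[chrom]:
                raise ValidationError(
                    f"interval on {chrom} extends past chromosome end ({sizes[chrom]})"
                )


# -- module-level operation surface ------------------------------------


def normalize(raw: Iterable[Record]) -> IntervalSet:
    """Sort, validate and merge raw (chrom, start, end) records."""
    return IntervalSet.from_records(raw)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.union(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def coverage_fraction(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of A's bases that lie inside B: bp(A∩B)/bp(A)."""
    denom = a.total_bp
    if denom == 0:
        raise ValidationError("coverage_fraction undefined for an empty query set")
    return a.intersect(b).total_bp / denom


def count_overlapping(
    peaks: Iterable[Record], b: IntervalSet, min_bp: int = 1
) -> int:
    """Number of peaks sharing at least *min_bp* bases with B."""
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    n = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peaks:
        if s >= e:
            raise ValidationError(f"empty/inverted peak ({chrom},{s},{e})")
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, lst in by_chrom.items():
        arr = np.asarray(lst, dtype=np.int64)
        ov = b.overlap_bp(chrom, arr[:, 0], arr[:, 1])
        n += int(np.sum(ov >= min_bp))
    return n


# -- BED3 I/O ----------------------------------------------------------


def read_bed3(path: str | Path) -> IntervalSet:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinate") from exc
    return normalize(records)


def write_bed3(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in iset.records():
            fh.write(f"{chrom}\t{s}\t{e}\n")
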