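"""Synthetic genomes with planted chromatin structure.

Generates every input the pipeline consumes — chromosome sizes, a
pericentromeric map, TSS-annotated genes, a five-colour chromatin
segmentation, a curated region→gene map, differential peak sets,
HP1/H3K9me3-like domain tracks and a differential-expression table —
with known ground truth, so each stage can be validated end to end
without sequencing data.

Geometry is deliberately simple: each chromosome carries a single
heterochromatin block at its right end (centromere-proximal), sized so
the genome-wide heterochromatic fraction f_het is exact to rounding.
Peaks choose heterochromatin with per-peak probability θ and are placed
uniformly, fully inside the chosen compartment.  Domain tracks are
unions of ~2 kb blocks constructed to hit a target genome coverage g
with a fraction h of their bases inside heterochromatin, both exact to
rounding.  All randomness flows from one root seed, split per artifact,
so adding a peak set never perturbs gene placement.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleSimError, ValidationError
from .genome_model import (
    ArmBoundary,
    BoundarySpec,
    ChromSizes,
    ChromatinState,
    ChromatinStateMap,
    CuratedRegionMap,
    GeneAnnotation,
    GeneRecord,
    PericentromericMap,
    Side,
    build_pericentromeric_map,
    write_chrom_sizes,
    write_curated,
    write_genes,
    write_states,
)
from .intervals import IntervalSet, write_bed3
from .peakio import Assay, Direction, PeakRecord, PeakTable, write_peaks

__all__ = [
    "PeakSetSpec",
    "TrackSpec",
    "ExpressionSpec",
    "SimSpec",
    "SimResult",
    "simulate",
    "calibrated_spec",
]

DEFAULT_STATE_PROPS = {
    "BLACK": 0.20,
    "BLUE": 0.10,
    "GREEN": 0.10,
    "YELLOW": 0.25,
    "RED": 0.20,
    "UNASSIGNED": 0.15,
}

HET_STATES = (ChromatinState.BLACK, ChromatinState.BLUE, ChromatinState.GREEN)
EU_STATES = (ChromatinState.YELLOW, ChromatinState.RED)


@dataclass(frozen=True)
class PeakSetSpec:
    """A planted differential peak set."""

    label: str
    assay: Assay
    n_peaks: int
    theta_het: float  # per-peak probability of heterochromatic placement
    direction_mix: dict = field(default_factory=lambda: {"UP": 0.5, "DOWN": 0.5})
    tier_mix: dict = field(
        default_factory=lambda: {0.05: 0.42, 0.01: 0.28, 0.001: 0.30}
    )
    length_median: float = 500.0  # log-normal, bp
    length_sigma: float = 0.5


@dataclass(frozen=True)
class TrackSpec:
    """An HP1/H3K9me3-like domain track."""

    label: str
    coverage: float  # g: fraction of the genome covered
    het_concentration: float  # h: fraction of track bp inside heterochromatin


@dataclass(frozen=True)
class ExpressionSpec:
    fraction_expressed: float = 0.55
    n_up: int = 60
    n_down: int = 45
    effect_size: float = 2.0  # |log2FC| for planted genes
    noise_sd: float = 0.3


@dataclass(frozen=True)
class SimSpec:
    seed: int
    chrom_lengths: dict
    f_het: float = 0.141
    n_genes: int = 400
    tss_het_bias: float = 0.02
    state_props: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PROPS))
    peak_sets: tuple[PeakSetSpec, ...] = ()
    tracks: tuple[TrackSpec, ...] = ()
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    curated_fraction: float = 0.10  # fraction of genes given a curated region

    def validate(self) -> None:
        if not 0 <= self.f_het <= 1:
            raise InfeasibleSimError("f_het must lie in [0,1]")
        if not 0 <= self.tss_het_bias <= 1:
            raise InfeasibleSimError("tss_het_bias must lie in [0,1]")
        if abs(sum(self.state_props.values()) - 1) > 1e-9:
            raise InfeasibleSimError("state proportions must sum to 1")
        for ps in self.peak_sets:
            if not 0 <= ps.theta_het <= 1:
                raise InfeasibleSimError(f"{ps.label}: theta_het outside [0,1]")
            if self.f_het == 0 and ps.theta_het > 0:
                raise InfeasibleSimError(
                    f"{ps.label}: theta_het>0 with no heterochromatin (f_het=0)"
                )
            if self.f_het == 1 and ps.theta_het < 1:
                raise InfeasibleSimError(
                    f"{ps.label}: theta_het<1 with no euchromatin (f_het=1)"
                )
            for mix, name in ((ps.direction_mix, "direction"), (ps.tier_mix, "tier")):
                if abs(sum(mix.values()) - 1) > 1e-9:
                    raise InfeasibleSimError(f"{ps.label}: {name} mix must sum to 1")
        for tr in self.tracks:
            if not 0 <= tr.coverage <= 1 or not 0 <= tr.het_concentration <= 1:
                raise InfeasibleSimError(f"{tr.label}: g and h must lie in [0,1]")
            if tr.coverage * tr.het_concentration > self.f_het + 1e-12:
                raise InfeasibleSimError(
                    f"{tr.label}: g*h={tr.coverage * tr.het_concentration:.4f} "
                    f"exceeds f_het={self.f_het} (track cannot put more bp in "
                    "heterochromatin than heterochromatin contains)"
                )
            if tr.coverage * (1 - tr.het_concentration) > 1 - self.f_het + 1e-12:
                raise InfeasibleSimError(
                    f"{tr.label}: euchromatic share exceeds euchromatin size"
                )


@dataclass
class SimResult:
    spec: SimSpec
    sizes: ChromSizes
    boundaries: BoundarySpec
    pericentromere: PericentromericMap
    genes: GeneAnnotation
    gene_spans: dict
    states: ChromatinStateMap
    curated: CuratedRegionMap
    peak_tables: dict  # label -> PeakTable
    tracks: dict  # label -> IntervalSet
    expression: pd.DataFrame
    realized: dict
    paths: dict = field(default_factory=dict)


def _rng_for(seed: int, artifact: str) -> np.random.Generator:
    """Independent stream per artifact, stable under spec growth."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(artifact.encode())])
    )


def _compartment_position(
    rng: np.random.Generator, compartment: IntervalSet, length: int = 1
) -> tuple[str, int]:
    """Uniform placement of a *length*-bp span fully inside a compartment."""
    choices = []
    weights = []
    for chrom, s, e in compartment.records():
        room = (e - s) - length + 1
        if room > 0:
            choices.append((chrom, s))
            weights.append(room)
    if not choices:
        raise InfeasibleSimError(
            f"no compartment interval can hold a {length} bp feature"
        )
    w = np.asarray(weights, dtype=float)
    i = rng.choice(len(choices), p=w / w.sum())
    chrom, s = choices[i]
    return chrom, s + int(rng.integers(0, weights[i]))


def _build_het(sizes: ChromSizes, f_het: float) -> BoundarySpec:
    """One right-end heterochromatin block per chromosome, exact total."""
    total_target = round(f_het * sizes.total_bp)
    per = {c: int(f_het * sizes[c]) for c in sizes}
    deficit = total_target - sum(per.values())
    for c in sorted(sizes, key=lambda c: -sizes[c]):
        if deficit == 0:
            break
        room = sizes[c] - per[c]
        add = min(deficit, room)
        per[c] += add
        deficit -= add
    arms = []
    whole = set()
    for c in sizes:
        if per[c] == 0:
            continue
        if per[c] >= sizes[c]:
            whole.add(c)
        else:
            arms.append(ArmBoundary(c, sizes[c] - per[c], Side.RIGHT_OF_BOUNDARY))
    return BoundarySpec(tuple(arms), frozenset(whole))


def _genome_interval_set(sizes: ChromSizes) -> IntervalSet:
    return IntervalSet.from_records((c, 0, sizes[c]) for c in sizes)


def _simulate_genes(
    rng: np.random.Generator,
    spec: SimSpec,
    sizes: ChromSizes,
    het: IntervalSet,
    eu: IntervalSet,
) -> tuple[GeneAnnotation, dict]:
    records = []
    spans = {}
    width = len(str(max(spec.n_genes - 1, 1)))
    for i in range(spec.n_genes):
        in_het = rng.random() < spec.tss_het_bias and het.total_bp > 0
        comp = het if in_het else eu
        if comp.total_bp == 0:
            comp = het if het.total_bp else eu
        chrom, tss = _compartment_position(rng, comp, 1)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i:0{width}d}"
        length = int(rng.integers(500, 3001))
        if strand == "+":
            start, end = tss, min(tss + length, sizes[chrom])
        else:
            start, end = max(tss + 1 - length, 0), tss + 1
        records.append(GeneRecord(gid, chrom, strand, tss))
        spans[gid] = (start, end)
    return GeneAnnotation(records, sizes=sizes), spans


def _simulate_states(
    rng: np.random.Generator, spec: SimSpec, het: IntervalSet, eu: IntervalSet
) -> ChromatinStateMap:
    """Tile each compartment with 2–10 kb segments; leave UNASSIGNED gaps.

    Heterochromatic segments draw from {BLACK,BLUE,GREEN}, euchromatic
    from {YELLOW,RED}, with compartment-conditional renormalized
    proportions from ``spec.state_props``.
    """
    p_un = spec.state_props.get("UNASSIGNED", 0.0)
    segments = []
    for comp, palette in ((het, HET_STATES), (eu, EU_STATES)):
        probs = np.asarray([spec.state_props[s.value] for s in palette], dtype=float)
        if probs.sum() == 0:
            continue
        probs = probs / probs.sum()
        for chrom, s, e in comp.records():
            pos = s
            while pos < e:
                seg_len = int(rng.integers(2000, 10001))
                seg_end = min(pos + seg_len, e)
                if rng.random() >= p_un:
                    state = palette[rng.choice(len(palette), p=probs)]
                    segments.append((chrom, pos, seg_end, state))
                pos = seg_end
    return ChromatinStateMap(segments)


def _simulate_curated(
    rng: np.random.Generator,
    spec: SimSpec,
    sizes: ChromSizes,
    genes: GeneAnnotation,
) -> CuratedRegionMap:
    n = max(1, int(round(spec.curated_fraction * len(genes))))
    picked = rng.choice(len(genes.records), size=min(n, len(genes.records)), replace=False)
    records = []
    for i in sorted(picked):
        rec = genes.records[i]
        length = int(rng.integers(200, 801))
        offset = int(rng.integers(-2000, 2001))
        start = max(0, rec.tss + offset)
        end = min(start + length, sizes[rec.chrom])
        if end <= start:
            continue
        gene_ids = {rec.gene_id}
        if rng.random() < 0.2:  # occasional multi-gene region
            j = int(rng.integers(0, len(genes.records)))
            gene_ids.add(genes.records[j].gene_id)
        records.append((rec.chrom, start, end, frozenset(gene_ids)))
    return CuratedRegionMap(records, sizes=sizes)


def _simulate_peak_set(
    rng: np.random.Generator,
    ps: PeakSetSpec,
    sizes: ChromSizes,
    het: IntervalSet,
    eu: IntervalSet,
) -> tuple[PeakTable, dict]:
    dirs = sorted(ps.direction_mix)
    dir_p = np.asarray([ps.direction_mix[d] for d in dirs], dtype=float)
    tiers = sorted(ps.tier_mix)
    tier_p = np.asarray([ps.tier_mix[t] for t in tiers], dtype=float)
    max_room = max(
        (e - s for comp in (het, eu) if comp.total_bp for _, s, e in comp.records()),
        default=0,
    )
    records = []
    n_het = 0
    for i in range(ps.n_peaks):
        length = int(round(rng.lognormal(np.log(ps.length_median), ps.length_sigma)))
        length = max(50, min(length, max_room))
        in_het = rng.random() < ps.theta_het
        comp = het if in_het else eu
        chrom, start = _compartment_position(rng, comp, length)
        n_het += int(in_het)
        direction = Direction(dirs[rng.choice(len(dirs), p=dir_p)])
        tier = tiers[rng.choice(len(tiers), p=tier_p)]
        records.append(
            PeakRecord(
                chrom=chrom,
                start=start,
                end=start + length,
                direction=direction,
                fdr_tier=tier,
                assay=ps.assay,
                peak_id=f"{ps.label}_{i}",
            )
        )
    # identical spans in both directions would violate table invariants;
    # vanishingly unlikely, resolved by shaving one bp off the duplicate
    seen: dict[tuple, Direction] = {}
    for idx, rec in enumerate(records):
        key = (rec.chrom, rec.start, rec.end)
        while key in seen and seen[key] is not rec.direction:
            rec = replace(rec, start=rec.start + 1)
            key = (rec.chrom, rec.start, rec.end)
            records[idx] = rec
        seen[key] = rec.direction
    table = PeakTable(records, ps.assay, label=ps.label, sizes=sizes)
    realized_theta = n_het / ps.n_peaks if ps.n_peaks else 0.0
    return table, {"theta_het": realized_theta, "n_peaks": ps.n_peaks}


def _exact_blocks(
    rng: np.random.Generator,
    compartment: IntervalSet,
    target_bp: int,
    block_len: int = 2000,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping blocks totalling exactly *target_bp* bp."""
    if target_bp == 0:
        return []
    comp = list(compartment.records())
    lens = np.asarray([e - s for _, s, e in comp], dtype=np.int64)
    if target_bp > lens.sum():
        raise InfeasibleSimError("track target exceeds compartment size")
    # proportional allocation with largest-remainder correction
    quota = target_bp * lens / lens.sum()
    alloc = np.floor(quota).astype(np.int64)
    order = np.argsort(-(quota - alloc))
    for i in order[: target_bp - int(alloc.sum())]:
        alloc[i] += 1
    # rebalance any allocation exceeding its interval
    for i in np.argsort(-lens):
        if alloc[i] > lens[i]:
            excess = alloc[i] - lens[i]
            alloc[i] = lens[i]
            for j in np.argsort(-(lens - alloc)):
                take = min(excess, lens[j] - alloc[j])
                alloc[j] += take
                excess -= take
                if excess == 0:
                    break
    blocks = []
    for (chrom, s, e), b in zip(comp, alloc.tolist()):
        if b == 0:
            continue
        size = e - s
        k = max(1, int(round(b / block_len)))
        base, rem = divmod(b, k)
        lengths = [base + (1 if i < rem else 0) for i in range(k)]
        lengths = [x for x in lengths if x > 0]
        free = size - b
        gaps = rng.multinomial(free, np.full(len(lengths) + 1, 1 / (len(lengths) + 1)))
        pos = s
        for g, ln in zip(gaps[:-1], lengths):
            pos += int(g)
            blocks.append((chrom, pos, pos + ln))
            pos += ln
    return blocks


def _simulate_track(
    rng: np.random.Generator,
    tr: TrackSpec,
    sizes: ChromSizes,
    het: IntervalSet,
    eu: IntervalSet,
) -> tuple[IntervalSet, dict]:
    total = round(tr.coverage * sizes.total_bp)
    in_het = round(tr.coverage * tr.het_concentration * sizes.total_bp)
    in_eu = total - in_het
    blocks = _exact_blocks(rng, het, in_het) + _exact_blocks(rng, eu, in_eu)
    track = IntervalSet.from_records(blocks)
    realized_g = track.total_bp / sizes.total_bp
    realized_h = (
        track.intersect(het).total_bp / track.total_bp if track.total_bp else 0.0
    )
    return track, {"g": realized_g, "h": realized_h}


def _simulate_expression(
    rng: np.random.Generator, spec: SimSpec, genes: GeneAnnotation
) -> tuple[pd.DataFrame, dict]:
    ex = spec.expression
    ids = [r.gene_id for r in genes.records]
    n = len(ids)
    if ex.n_up + ex.n_down > n:
        raise InfeasibleSimError("planted UP+DOWN gene counts exceed n_genes")
    planted = rng.choice(n, size=ex.n_up + ex.n_down, replace=False)
    up_idx = set(planted[: ex.n_up].tolist())
    down_idx = set(planted[ex.n_up :].tolist())
    rows = []
    for i, gid in enumerate(ids):
        if i in up_idx:
            lfc = rng.normal(ex.effect_size, ex.noise_sd)
            fdr = rng.uniform(0.0, 0.01)
        elif i in down_idx:
            lfc = rng.normal(-ex.effect_size, ex.noise_sd)
            fdr = rng.uniform(0.0, 0.01)
        else:
            lfc = rng.normal(0.0, ex.noise_sd)
            fdr = rng.uniform(0.0, 1.0)
        expressed = rng.random() < ex.fraction_expressed
        tpm = float(np.exp(rng.normal(2.5, 1.0))) if expressed else float(rng.uniform(0, 1))
        rows.append(
            {
                "gene_id": gid,
                "log2fc": round(float(lfc), 4),
                "significance": round(float(fdr), 6),
                "tpm": round(tpm, 3),
            }
        )
    df = pd.DataFrame(rows)
    realized = {
        "n_planted_up": ex.n_up,
        "n_planted_down": ex.n_down,
        "fraction_expressed": float((df["tpm"] >= 1.0).mean()),
    }
    return df, realized


def simulate(spec: SimSpec, outdir: str | Path | None = None) -> SimResult:
    """Generate all artifacts; optionally write them plus a manifest."""
    spec.validate()
    sizes = ChromSizes(spec.chrom_lengths)
    boundaries = _build_het(sizes, spec.f_het)
    peri = build_pericentromeric_map(boundaries, sizes)
    het = peri.intervals
    eu = _genome_interval_set(sizes).subtract(het)

    genes, spans = _simulate_genes(_rng_for(spec.seed, "genes"), spec, sizes, het, eu)
    states = _simulate_states(_rng_for(spec.seed, "states"), spec, het, eu)
    curated = _simulate_curated(_rng_for(spec.seed, "curated"), spec, sizes, genes)

    peak_tables: dict[str, PeakTable] = {}
    realized: dict = {
        "f_het": peri.genome_fraction,
        "het_bp": peri.total_bp,
        "genome_bp": sizes.total_bp,
        "peak_sets": {},
        "tracks": {},
    }
    for ps in spec.peak_sets:
        table, summary = _simulate_peak_set(
            _rng_for(spec.seed, f"peaks:{ps.label}"), ps, sizes, het, eu
        )
        peak_tables[ps.label] = table
        realized["peak_sets"][ps.label] = summary

    tracks: dict[str, IntervalSet] = {}
    for tr in spec.tracks:
        track, summary = _simulate_track(
            _rng_for(spec.seed, f"track:{tr.label}"), tr, sizes, het, eu
        )
        tracks[tr.label] = track
        realized["tracks"][tr.label] = summary

    expression, ex_summary = _simulate_expression(
        _rng_for(spec.seed, "expression"), spec, genes
    )
    realized["expression"] = ex_summary

    result = SimResult(
        spec=spec,
        sizes=sizes,
        boundaries=boundaries,
        pericentromere=peri,
        genes=genes,
        gene_spans=spans,
        states=states,
        curated=curated,
        peak_tables=peak_tables,
        tracks=tracks,
        expression=expression,
        realized=realized,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: SimResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[str]] = {}

    p = outdir / "chrom_sizes.tsv"
    write_chrom_sizes(result.sizes, p)
    paths["chrom_sizes"] = [p.name]

    p = outdir / "genes.refflat.tsv"
    write_genes(result.genes, p, spans=result.gene_spans)
    paths["genes"] = [p.name]

    p = outdir / "states.bed"
    write_states(result.states, p)
    paths["states"] = [p.name]

    p = outdir / "curated.bed"
    write_curated(result.curated, p)
    paths["curated"] = [p.name]

    paths["peaks"] = []
    for label, table in result.peak_tables.items():
        p = outdir / f"peaks.{label}.bed"
        write_peaks(table, p)
        paths["peaks"].append(p.name)

    paths["tracks"] = []
    for label, track in result.tracks.items():
        p = outdir / f"track.{label}.bed"
        write_bed3(track, p)
        paths["tracks"].append(p.name)

    p = outdir / "expression.tsv"
    result.expression.to_csv(p, sep="\t", index=False)
    paths["expression"] = [p.name]

    manifest = {
        "seed": result.spec.seed,
        "artifacts": {
            kind: {"files": files} for kind, files in paths.items()
        },
        "realized": result.realized,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.paths = {k: [str(outdir / f) for f in v] for k, v in paths.items()}
    result.paths["manifest"] = [str(outdir / "manifest.json")]


def calibrated_spec(seed: int = 0) -> SimSpec:
    """Default spec calibrated to the study's headline fractions.

    10 Mb toy genome; pericentromeric fraction 0.141; ATAC-UP peaks
    placed in heterochromatin with probability 0.221 versus 0.141 for
    ATAC-DOWN (the background rate); HP1-like track covering 11.8% and
    H3K9me3-like track covering 14.5% of the genome, each with 35% of
    their bases pericentromeric.  ATAC peak counts (908 UP / 653 DOWN)
    give the study's UP/DOWN ratio of 1.39 at the strictest tier-style
    accounting; H3K27ac sets are smaller, as ChIP changes were fewer.
    """
    chroms = {
        "chrT1": 3_000_000,
        "chrT2": 2_600_000,
        "chrT3": 2_400_000,
        "chrT4": 1_400_000,
        "chrTX": 600_000,
    }
    return SimSpec(
        seed=seed,
        chrom_lengths=chroms,
        f_het=0.141,
        n_genes=400,
        tss_het_bias=0.02,
        peak_sets=(
            PeakSetSpec(
                "ATAC-UP", Assay.ATAC, 908, 0.221, direction_mix={"UP": 1.0}
            ),
            PeakSetSpec(
                "ATAC-DOWN", Assay.ATAC, 653, 0.141, direction_mix={"DOWN": 1.0}
            ),
            PeakSetSpec(
                "H3K27ac-UP", Assay.H3K27AC, 400, 0.141, direction_mix={"UP": 1.0}
            ),
            PeakSetSpec(
                "H3K27ac-DOWN", Assay.H3K27AC, 350, 0.141, direction_mix={"DOWN": 1.0}
            ),
        ),
        tracks=(
            TrackSpec("HP1", 0.118, 0.35),
            TrackSpec("H3K9me3", 0.145, 0.35),
        ),
        expression=ExpressionSpec(),
    )
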