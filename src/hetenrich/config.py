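"""Structured run configuration (YAML) with a validated schema.

Unknown keys are rejected so silent typos cannot change an analysis.
The same file drives both the simulator (``sim:`` section) and the
analysis pipeline (``inputs:``/``boundaries:``/``thresholds:``).
Relative input paths are resolved against the config file's directory.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError
from .genome_model import ArmBoundary, BoundarySpec, Side
from .peakio import Assay
from .synthetic_data import (
    ExpressionSpec,
    PeakSetSpec,
    SimSpec,
    TrackSpec,
    calibrated_spec,
)

__all__ = ["RunConfig", "load_config", "config_hash", "build_sim_spec", "build_boundary_spec"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PeakInput(_Model):
    path: str
    assay: str
    label: str = ""
    dialect: str = "bed6plus"


class TrackInput(_Model):
    path: str
    label: str


class Inputs(_Model):
    chrom_sizes: str
    genes: str
    genes_dialect: str = "refflat"
    states: str | None = None
    curated: str | None = None
    expression: str | None = None
    peaks: list[PeakInput] = Field(default_factory=list)
    tracks: list[TrackInput] = Field(default_factory=list)


class ArmConfig(_Model):
    chrom: str
    boundary: int
    side: str

    @field_validator("side")
    @classmethod
    def _check_side(cls, v: str) -> str:
        if v not in (s.value for s in Side):
            raise ValueError(f"side must be one of {[s.value for s in Side]}")
        return v


class Boundaries(_Model):
    arms: list[ArmConfig] = Field(default_factory=list)
    whole_chromosomes: list[str] = Field(default_factory=list)


class Thresholds(_Model):
    alpha: float = 0.05
    min_bp: int = 1
    log2fc: float = 0.4
    significance: float = 0.05
    significance_kind: str = "FDR"
    tpm_cutoff: float = 1.0


class PeakSetConfig(_Model):
    label: str
    assay: str
    n_peaks: int
    theta_het: float
    direction_mix: dict[str, float] = Field(default_factory=lambda: {"UP": 0.5, "DOWN": 0.5})
    tier_mix: dict[float, float] = Field(
        default_factory=lambda: {0.05: 0.42, 0.01: 0.28, 0.001: 0.30}
    )
    length_median: float = 500.0
    length_sigma: float = 0.5


class TrackConfig(_Model):
    label: str
    coverage: float
    het_concentration: float


class ExpressionConfig(_Model):
    fraction_expressed: float = 0.55
    n_up: int = 60
    n_down: int = 45
    effect_size: float = 2.0
    noise_sd: float = 0.3


class SimConfig(_Model):
    calibrated: bool = False
    chrom_lengths: dict[str, int] = Field(default_factory=dict)
    f_het: float = 0.141
    n_genes: int = 400
    tss_het_bias: float = 0.02
    state_props: dict[str, float] | None = None
    peak_sets: list[PeakSetConfig] = Field(default_factory=list)
    tracks: list[TrackConfig] = Field(default_factory=list)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)
    curated_fraction: float = 0.10


class RunConfig(_Model):
    seed: int = 0
    outdir: str | None = None
    inputs: Inputs | None = None
    boundaries: Boundaries = Field(default_factory=Boundaries)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    sim: SimConfig | None = None
    base_dir: Path | None = Field(default=None, exclude=True)

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ValidationError(f"{path}: {exc}") from exc
    cfg.base_dir = path.parent
    return cfg


def config_hash(path: str | Path) -> str:
    """Stable hash of the canonicalized config content."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    canon = yaml.safe_dump(raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_boundary_spec(cfg: RunConfig) -> BoundarySpec:
    return BoundarySpec(
        arms=tuple(
            ArmBoundary(a.chrom, a.boundary, Side(a.side)) for a in cfg.boundaries.arms
        ),
        whole_chromosomes=frozenset(cfg.boundaries.whole_chromosomes),
    )


def build_sim_spec(cfg: RunConfig, seed: int | None = None) -> SimSpec:
    if cfg.sim is None:
        raise ValidationError("config has no 'sim' section")
    use_seed = cfg.seed if seed is None else seed
    if cfg.sim.calibrated:
        return calibrated_spec(seed=use_seed)
    sc = cfg.sim
    if not sc.chrom_lengths:
        raise ValidationError("sim.chrom_lengths is required unless calibrated")
    kwargs = {}
    if sc.state_props is not None:
        kwargs["state_props"] = sc.state_props
    return SimSpec(
        seed=use_seed,
        chrom_lengths=sc.chrom_lengths,
        f_het=sc.f_het,
        n_genes=sc.n_genes,
        tss_het_bias=sc.tss_het_bias,
        peak_sets=tuple(
            PeakSetSpec(
                label=p.label,
                assay=Assay(p.assay),
                n_peaks=p.n_peaks,
                theta_het=p.theta_het,
                direction_mix=p.direction_mix,
                tier_mix=p.tier_mix,
                length_median=p.length_median,
                length_sigma=p.length_sigma,
            )
            for p in sc.peak_sets
        ),
        tracks=tuple(
            TrackSpec(t.label, t.coverage, t.het_concentration) for t in sc.tracks
        ),
        expression=ExpressionSpec(**sc.expression.model_dump()),
        curated_fraction=sc.curated_fraction,
        **kwargs,
    )
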