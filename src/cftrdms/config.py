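"""Run configuration: one YAML document drives a full pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

ALL_STAGES = ("simulate", "score", "respond", "interactome", "kinetics")


@dataclass
class Thresholds:
    variation: float = 0.40       # reject scores differing by >40% across iterations
    curve_c: float = 0.8          # curvature of the reciprocal interactor filter
    sigma_multiplier: float = 2.0  # fold-change cutoff x0 = multiplier * sigma
    ratio_floor: float = 0.0      # minimum vehicle PME for a response ratio

    def validate(self) -> None:
        for name in ("variation", "curve_c", "sigma_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.ratio_floor < 0:
            raise ValueError("ratio_floor must be >= 0")


@dataclass
class SortSeqSection:
    n_variants: int = 40
    cells_per_pool: int = 20_000
    reads_per_fraction: int = 30_000
    seq_error_rate: float = 0.001
    ko_attenuation: float = 0.26
    corrector_fold: float = 2.0     # applied to the most attenuated third of variants
    n_replicates: int = 3


@dataclass
class InteractomeSection:
    n_proteins: int = 1200
    n_true_interactors: int = 30
    background_sigma: float = 0.5
    effect_size: float = 2.5
    n_replicates: int = 3
    literal_p: bool = False


@dataclass
class KineticsSection:
    k1: float = 0.02
    y0: float = 0.2
    A1: float = 1.0
    noise_sd: float = 0.05
    n_cells: int = 2000
    t_max: float = 200.0
    n_replicates: int = 3


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: Thresholds = field(default_factory=Thresholds)
    sort_seq: SortSeqSection = field(default_factory=SortSeqSection)
    interactome: InteractomeSection = field(default_factory=InteractomeSection)
    kinetics: KineticsSection = field(default_factory=KineticsSection)
    # optional external inputs for the score stage (otherwise simulated)
    counts_path: str | None = None
    whitelist_path: str | None = None
    fraction_means_path: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st!r}")
        self.thresholds.validate()
        for p in (self.counts_path, self.whitelist_path, self.fraction_means_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        for key, typ in (
            ("thresholds", Thresholds),
            ("sort_seq", SortSeqSection),
            ("interactome", InteractomeSection),
            ("kinetics", KineticsSection),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
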