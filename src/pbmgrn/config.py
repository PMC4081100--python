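"""Pipeline configuration: thresholds, scoring, seeds and paths.

Defaults are the workflow's canonical operating points: words with
ES >= 0.40 are significant, promoter-scanning seeds need ES > 0.45,
co-expression clusters hold the top 100 Pearson neighbors and are tested
at P < 0.05, and footprint significance uses 1000 resampled non-orthologous
gene sets at FDR < 5%.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .footprint import AlignScoring

__all__ = ["Thresholds", "KmerSettings", "PipelineConfig"]


@dataclass
class Thresholds:
    es_significant: float = 0.40
    es_seed: float = 0.45
    coexp_top_n: int = 100
    coexp_alpha: float = 0.05
    fdr_alpha: float = 0.05
    n_null_samples: int = 1000

    def validate(self) -> None:
        if not -0.5 <= self.es_significant <= 0.5:
            raise ValueError(f"es_significant out of [-0.5, 0.5]: {self.es_significant}")
        if not -0.5 <= self.es_seed <= 0.5:
            raise ValueError(f"es_seed out of [-0.5, 0.5]: {self.es_seed}")
        if self.coexp_top_n < 1:
            raise ValueError("coexp_top_n must be >= 1")
        for name in ("coexp_alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1): {v}")
        if self.n_null_samples < 1:
            raise ValueError("n_null_samples must be >= 1")


@dataclass
class KmerSettings:
    k: int = 8
    max_gap: int = 1
    min_foreground: int = 4

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_foreground < 1:
            raise ValueError("min_foreground must be >= 1")


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    kmer: KmerSettings = field(default_factory=KmerSettings)
    aligner: AlignScoring = field(default_factory=AlignScoring)
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    footprint_tfs: list[str] | None = None  # None = all TFs

    def validate(self) -> None:
        self.thresholds.validate()
        self.kmer.validate()
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "kmer" in kwargs:
            kwargs["kmer"] = KmerSettings(**kwargs["kmer"])
        if "aligner" in kwargs:
            kwargs["aligner"] = AlignScoring(**kwargs["aligner"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
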