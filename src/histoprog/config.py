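"""Run configuration: one nested, JSON-round-trippable config for the whole
pipeline, with a single global seed feeding named substreams everywhere."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .nn import EncoderConfig
from .survmodel import TrainConfig
from .synthdata import CohortConfig

__all__ = ["RoiConfig", "EvalConfig", "ExplainConfig", "RunConfig"]


@dataclass
class RoiConfig:
    target_recall: float = 0.90
    radius: int = 2  # dilation radius in superpixels (desk scale; 0/4/16 at full scale)
    min_component: int = 8
    connectivity: int = 8
    heatmap_noise: float = 0.05  # sigma of superpixel probability noise
    use_classifier: bool = False  # heatmaps from a trained patch classifier

    def validate(self) -> None:
        if not 0 < self.target_recall <= 1:
            raise ValueError("target_recall must lie in (0, 1]")
        if self.radius < 0 or self.min_component < 1:
            raise ValueError("radius must be >= 0 and min_component >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class EvalConfig:
    horizon: int = 60
    n_boot: int = 200

    def validate(self) -> None:
        if self.horizon < 1 or self.n_boot < 0:
            raise ValueError("horizon must be >= 1 and n_boot >= 0")


@dataclass
class ExplainConfig:
    embedder: str = "texture"  # or "encoder"
    sample_patches: int = 2000  # training-split embedding sample (100k at full scale)
    k_grid: tuple = (4, 8, 16)
    n_select: int = 10
    patch_score_sample: int = 1500
    n_boot: int = 500

    def validate(self) -> None:
        if self.embedder not in ("texture", "encoder"):
            raise ValueError("embedder must be 'texture' or 'encoder'")
        if not self.k_grid:
            raise ValueError("k_grid must be non-empty")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_models: int = 2
    eval: EvalConfig = field(default_factory=EvalConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    split_ratios: tuple = (2, 1, 1)  # train : tune : val1
    val2_fraction: float = 0.2  # temporal hold-out share
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.roi.validate()
        self.train.validate()
        self.eval.validate()
        self.explain.validate()
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if len(self.split_ratios) != 3 or any(r <= 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be three positive numbers")
        if not 0 <= self.val2_fraction < 1:
            raise ValueError("val2_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = CohortConfig.from_dict(d.get("cohort", {}))
        roi = d.get("roi", {})
        d["roi"] = roi if isinstance(roi, RoiConfig) else RoiConfig(**roi)
        ev = d.get("eval", {})
        d["eval"] = ev if isinstance(ev, EvalConfig) else EvalConfig(**ev)
        ex = dict(d.get("explain", {}))
        if "k_grid" in ex:
            ex["k_grid"] = tuple(ex["k_grid"])
        d["explain"] = ExplainConfig(**ex)
        tr = dict(d.get("train", {}))
        if "encoder" in tr and not isinstance(tr["encoder"], EncoderConfig):
            enc = dict(tr["encoder"])
            if "blocks" in enc:
                enc["blocks"] = tuple(tuple(b) for b in enc["blocks"])
            tr["encoder"] = EncoderConfig(**enc)
        d["train"] = TrainConfig(**tr)
        if "split_ratios" in d:
            d["split_ratios"] = tuple(d["split_ratios"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
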