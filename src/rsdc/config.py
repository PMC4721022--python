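"""Run-wide configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the defaults are the method's reference settings.

    alpha / u_alpha / sd_ddof parameterise the outlier band (0.05, 1.96,
    sample sd); B bounds the forward-selection scan (100); backend picks
    the scoring rule (rs); chi2_correction the 2x2 variant
    (yates_nofloor); pair_subset, when set, restricts integrated-ranking
    partners to the top-K individually scoring genes (off by default).
    """

    alpha: float = 0.05
    u_alpha: float | None = None
    sd_ddof: int = 1
    outlier_adjust: bool = True
    B: int = 100
    backend: str = "rs"
    chi2_correction: str = "yates_nofloor"
    class_order: tuple[str, ...] | None = None
    pair_subset: int | None = None
    label_column: str = "class"
    seed: int = 0
    verbosity: int = 0

    def preprocess(self) -> PreprocessConfig:
        return PreprocessConfig(
            alpha=self.alpha, u_alpha=self.u_alpha, sd_ddof=self.sd_ddof
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["class_order"] is not None:
            d["class_order"] = list(d["class_order"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("class_order") is not None:
            d["class_order"] = tuple(str(c) for c in d["class_order"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def merged(self, **overrides) -> "RunConfig":
        d = self.to_dict()
        d.update({k: v for k, v in overrides.items() if v is not None})
        return self.from_dict(d)
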