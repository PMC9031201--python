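"""Run configuration: one serializable object tying a whole run together.

A run config pins the detector parameters, optional preprocessing, the
evaluation settings and the seed, so that two processes given the same
config produce byte-identical reports.  Configs are read from TOML;
unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .core import NCAParams
from .preprocess import PreprocessParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    nca_params: NCAParams = field(default_factory=NCAParams)
    preprocess: PreprocessParams | None = None
    iou_threshold: float = 0.5
    match_mode: str = "marking"  # clinical accounting: the mark hits the lesion
    betas: tuple[float, ...] = (1.0, 10.0, 50.0, 100.0)
    rounding_mode: str = "truncate_2dp"
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.iou_threshold <= 1):
            raise ValueError("iou_threshold must lie in (0, 1]")
        if self.rounding_mode not in ("truncate_2dp", "round_2dp", "none"):
            raise ValueError(f"unknown rounding_mode {self.rounding_mode!r}")
        if self.match_mode not in ("iou", "marking"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))

    def to_dict(self) -> dict:
        d: dict = {
            "nca_params": {
                k: getattr(self.nca_params, k)
                for k in (
                    "k",
                    "k_divisions",
                    "min_depth",
                    "tau_area",
                    "tau_shift",
                    "polarity",
                    "min_area",
                    "max_area",
                    "max_area_fraction",
                )
            },
            "iou_threshold": self.iou_threshold,
            "match_mode": self.match_mode,
            "betas": list(self.betas),
            "rounding_mode": self.rounding_mode,
            "seed": self.seed,
            "input_dir": self.input_dir,
            "output_dir": self.output_dir,
        }
        if self.preprocess is not None:
            d["preprocess"] = {
                "low_fraction": self.preprocess.low_fraction,
                "high_fraction": self.preprocess.high_fraction,
                "clip_limit_1": self.preprocess.clip_limit_1,
                "clip_limit_2": self.preprocess.clip_limit_2,
                "tile_grid": list(self.preprocess.tile_grid),
            }
        return d


def _build(cls, raw: dict, where: str):
    import inspect

    allowed = set(inspect.signature(cls).parameters)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**raw)


def load_config(path: str | Path) -> RunConfig:
    """Parse a TOML run config, rejecting unknown keys."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top_allowed = {
        "nca_params",
        "preprocess",
        "iou_threshold",
        "match_mode",
        "betas",
        "rounding_mode",
        "seed",
        "input_dir",
        "output_dir",
    }
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown keys in {path}: {sorted(unknown)}")
    kwargs: dict = {k: v for k, v in raw.items() if k not in ("nca_params", "preprocess")}
    if "betas" in kwargs:
        kwargs["betas"] = tuple(kwargs["betas"])
    if "nca_params" in raw:
        kwargs["nca_params"] = _build(NCAParams, dict(raw["nca_params"]), "nca_params")
    if "preprocess" in raw:
        pp = dict(raw["preprocess"])
        if "tile_grid" in pp:
            pp["tile_grid"] = tuple(pp["tile_grid"])
        kwargs["preprocess"] = _build(PreprocessParams, pp, "preprocess")
    return RunConfig(**kwargs)
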