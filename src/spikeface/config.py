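"""Typed, validated configuration for the end-to-end pipeline.

The config is a flat key/value document (YAML on disk).  Unknown keys are
rejected at load time and every numeric field is checked against the
domain of the stage it feeds, so a typo fails fast rather than deep
inside a run.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the retina → V1 → TICA → spiking hierarchy."""

    # preprocessing
    mask_margin: float = 0.05
    illum_normalize: bool = True
    illum_method: str = "meanvar"
    # retina stage
    retina_sigmas: list[float] = field(default_factory=lambda: [1.0, 2.0])
    retina_gain: float = 1.0
    # V1 Gabor bank
    gabor_n_scales: int = 3
    gabor_sigma: float = 2.0 * math.pi
    gabor_kmax: float = math.pi / 2.0
    gabor_spacing: float = math.sqrt(2.0)
    v1_input: str = "on_plus_off"
    pool_block: int = 2
    # TICA stage
    patch_size: int = 8
    n_patches: int = 3000
    tica_components: int = 16
    tica_m: int = 1
    tica_topology: str = "ring"
    tica_alpha: float = 1.0
    tica_beta: float = 0.0
    tica_learn_rate: float = 0.25
    tica_n_iter: int = 200
    tica_tol: float = 1e-6
    # spiking output layer
    mod: float = 0.99
    keep_frac: float = 0.2
    threshold_margin: float = 0.9
    inhib_amplitude: float = 0.1
    inhib_radius: float = 2.0
    # evaluation
    split_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.mask_margin <= 0.4):
            raise ParameterError("mask_margin must lie in [0, 0.4]")
        if self.illum_method not in ("histeq", "meanvar"):
            raise ParameterError("illum_method must be 'histeq' or 'meanvar'")
        if not self.retina_sigmas or any(s <= 0 for s in self.retina_sigmas):
            raise ParameterError("retina_sigmas must be positive")
        if self.retina_gain <= 0:
            raise ParameterError("retina_gain must be positive")
        if self.gabor_n_scales < 1:
            raise ParameterError("gabor_n_scales must be >= 1")
        if self.gabor_sigma <= 0 or self.gabor_kmax <= 0:
            raise ParameterError("gabor_sigma and gabor_kmax must be positive")
        if self.gabor_spacing <= 1:
            raise ParameterError("gabor_spacing must exceed 1")
        if self.v1_input not in ("raw", "on_plus_off"):
            raise ParameterError("v1_input must be 'raw' or 'on_plus_off'")
        if self.pool_block < 1:
            raise ParameterError("pool_block must be >= 1")
        if self.patch_size < 2:
            raise ParameterError("patch_size must be >= 2")
        if self.n_patches < 10 * self.tica_components:
            raise ParameterError("n_patches must be >= 10 * tica_components")
        if self.tica_components < 2:
            raise ParameterError("tica_components must be >= 2")
        if self.tica_m < 0:
            raise ParameterError("tica_m must be >= 0")
        if self.tica_topology not in ("line", "ring", "grid"):
            raise ParameterError("tica_topology must be line, ring or grid")
        if self.tica_learn_rate <= 0 or self.tica_n_iter < 1:
            raise ParameterError("bad TICA optimizer settings")
        if not (0.0 < self.mod < 1.0):
            raise ParameterError("mod must lie strictly in (0, 1)")
        if not (0.0 < self.keep_frac <= 1.0):
            raise ParameterError("keep_frac must lie in (0, 1]")
        if self.threshold_margin < 0:
            raise ParameterError("threshold_margin must be non-negative")
        if self.inhib_amplitude < 0 or self.inhib_radius <= 0:
            raise ParameterError("bad inhibition settings")
        if not (0.0 < self.split_frac < 1.0):
            raise ParameterError("split_frac must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ParameterError("config file must hold a flat mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def with_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` strings; values parsed as YAML scalars."""
        d = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ParameterError(f"override {item!r} is not key=value")
            key, _, val = item.partition("=")
            if key not in d:
                raise ParameterError(f"unknown config key: {key!r}")
            d[key] = yaml.safe_load(val)
        return PipelineConfig.from_dict(d)
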