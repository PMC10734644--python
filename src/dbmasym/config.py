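"""Validated run configuration (YAML/JSON) for the command-line pipeline.

A minimal file like ``{seed: 1}`` expands to a fully-defaulted
configuration; unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .frameworks import FrameworkConfig
from .inference import InferenceConfig
from .phantom import PhantomSpec, spec_from_dict
from .registration import RegistrationConfig


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AsymSiteModel(_Strict):
    center: list[float]
    radius_mm: float = Field(gt=0)
    peak_factor: float = Field(gt=0)
    hemisphere: str = Field(pattern="^[LR]$")
    timing: str = Field(default="growth", pattern="^(growth|both)$")


class PhantomModel(_Strict):
    grid_shape: list[int] = [64, 64, 64]
    spacing_mm: float = Field(default=1.0, gt=0)
    global_scale: float = Field(default=1.3, gt=1.0, le=1.6)
    asym_sites: list[AsymSiteModel] = []
    noise_sd: float = Field(default=2.0, ge=0)
    seed: int = 0

    def to_spec(self) -> PhantomSpec:
        d = self.model_dump()
        return spec_from_dict(d)


class RegistrationModel(_Strict):
    levels: list[int] = [4, 2, 1]
    iters_per_level: list[int] = [100, 60, 30]
    smoothing_sigmas: list[float] = [2.0, 1.0, 0.5]
    similarity: str = "local_cross_correlation"
    lcc_radius: int = Field(default=2, ge=1)
    update_sigma: float = Field(default=1.5, ge=0)
    total_sigma: float = Field(default=1.0, ge=0)
    step_mm: float = Field(default=2.0, gt=0)
    histogram_match: bool = True

    def to_config(self) -> RegistrationConfig:
        d = self.model_dump()
        for k in ("levels", "iters_per_level", "smoothing_sigmas"):
            d[k] = tuple(d[k])
        return RegistrationConfig(**d)


class InferenceModel(_Strict):
    n_perm: int = Field(default=5000, ge=1)
    tfce_E: float = Field(default=0.5, ge=0)
    tfce_H: float = Field(default=2.0, ge=0)
    tfce_dh: float | None = Field(default=None, gt=0)
    tfce_n_steps: int = Field(default=100, ge=1)
    connectivity: int = 26
    alpha_threshold: float = Field(default=0.975, gt=0, lt=1)
    variance_smooth_fwhm_mm: float = Field(default=6.0, ge=0)
    seed: int = 0

    def to_config(self) -> InferenceConfig:
        return InferenceConfig(**self.model_dump())


class RunConfig(_Strict):
    seed: int
    n_subjects: int = Field(default=20, ge=2)
    framework: str = Field(default="both", pattern="^(A|B|both)$")
    out_dir: str = "dbmasym_out"
    log_level: str = "INFO"
    smooth_fwhm_mm: float = Field(default=3.0, ge=0)
    bleach: bool = True
    phantom: PhantomModel = Field(default_factory=PhantomModel)
    registration: RegistrationModel = Field(default_factory=RegistrationModel)
    inference: InferenceModel = Field(default_factory=InferenceModel)

    def framework_config(self) -> FrameworkConfig:
        inf = self.inference.to_config()
        inf.seed = self.seed if self.inference.seed == 0 else self.inference.seed
        return FrameworkConfig(
            registration=self.registration.to_config(),
            inference=inf,
            smooth_fwhm_mm=self.smooth_fwhm_mm,
            bleach=self.bleach)

    def phantom_spec(self) -> PhantomSpec:
        spec = self.phantom.to_spec()
        if self.phantom.seed == 0:
            spec.seed = self.seed
        return spec


def validate_config(path) -> RunConfig:
    """Load + schema-validate a YAML/JSON run configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config key '{loc}': {first['msg']}") from exc


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)
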