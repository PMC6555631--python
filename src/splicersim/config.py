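"""Validated run configurations for the canned experiments.

Configurations are nested YAML documents validated by pydantic models with
unknown keys rejected.  Every experiment writes its fully resolved
configuration next to its outputs so that any run can be reproduced from the
emitted file plus the seed alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .kspace import MotionModel
from .respiration import GateParams, RespModel
from .scheduler import ScanConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScanSection(_Section):
    tr: float = 2.0
    n_slices: int = 1
    n_pe: int = 64
    etl: int = 8
    loop_cap_factor: float = 4.0
    pe_ordering: str = "linear"

    def build(self) -> ScanConfig:
        return ScanConfig(**self.model_dump())


class RespSection(_Section):
    mu: float = 1.0
    sigma: float = 0.1
    breath_duration: float = 0.2
    drift_rate: float = 0.0
    double_breath_prob: float = 0.0

    def build(self) -> RespModel:
        return RespModel(**self.model_dump())


class GateSection(_Section):
    detection_latency: float = 0.05
    post_breath_extension: float = 0.15
    reacq_lookback: float = 0.15

    def build(self) -> GateParams:
        return GateParams(**self.model_dump())


class MotionSection(_Section):
    amplitude: float = 2.0

    def build(self) -> MotionModel:
        return MotionModel(amplitude=self.amplitude)


class SweepSection(_Section):
    """Grid for the scan-time sweep.

    The full-scale study grid is sigma from 0.2 % to 20 % of mu in 0.2 %
    steps, TR from 0.02 s to 4.0 s in 0.02 s steps and 1000 repeats per
    cell; the defaults here are a desk-scale grid covering the same ranges
    coarsely.
    """

    mu_values: list[float] = Field(default_factory=lambda: [1.0, 1.5, 2.0])
    sigma_frac_min: float = 0.02
    sigma_frac_max: float = 0.20
    n_sigma: int = 10
    tr_min: float = 0.1
    tr_max: float = 4.0
    n_tr: int = 40
    n_repeats: int = 100
    breath_duration: float = 0.5
    n_pe: int = 128


class DemoSection(_Section):
    matrix: int = 64
    fov: float = 32.0
    n_ungated: int = 20
    n_splicer: int = 10
    t1: float = 1.5
    flip: float = 90.0
    noise_sigma: float = 0.02
    roi_area: float = 128.0


class RunConfig(_Section):
    seed: int = 0
    outdir: str = "splicersim_out"
    scan: ScanSection = Field(default_factory=ScanSection)
    respiration: RespSection = Field(default_factory=RespSection)
    gate: GateSection = Field(default_factory=GateSection)
    motion: MotionSection = Field(default_factory=MotionSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    demo: DemoSection = Field(default_factory=DemoSection)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if ``path`` is None)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
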