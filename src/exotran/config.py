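"""Validated run configurations (TOML or JSON).

Configuration files use human-friendly units in field names (um/s, hours,
per-hour-per-1e5-cells); loading converts everything to SI and returns the
domain objects the solvers consume.  Unknown keys are rejected so typos
fail loudly, and a loaded config round-trips through ``to_dict``.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .benchmark import ShearBenchmarkParams
from .errors import ConfigurationError
from .geometry import CellLayout, generate_tme_layout
from .scenarios.transwell import RELEASE_RATE_NF, RELEASE_RATE_OF, TranswellConfig
from .scenarios.tme import TmeConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BenchmarkBlock(_Strict):
    U_m_s: float = 5.0e-6
    shear_rate_1_s: float = 5.0e-4
    M: float = 1.0
    D_m2_s: float = Field(1.0e-8, gt=0)
    t_init_s: float = Field(60.0, gt=0)
    duration_min: float = Field(45.0, gt=0)
    nx: int = Field(200, ge=4)
    scheme: Literal["upwind1", "upwind2", "quick", "muscl"] = "quick"
    cfl: float = Field(0.5, gt=0, le=1)
    variant: Literal["standard", "as_printed"] = "standard"

    def to_params(self) -> ShearBenchmarkParams:
        return ShearBenchmarkParams(
            U=self.U_m_s, lam=self.shear_rate_1_s, M=self.M, D=self.D_m2_s,
            t_init=self.t_init_s, duration=self.duration_min * 60.0,
            sign_variant=self.variant,
        )


class TranswellBlock(_Strict):
    condition: Literal["NF", "OF", "custom"] = "NF"
    per_cell_rate_per_h_per_1e5: float | None = Field(None, ge=0)
    cell_count: float = Field(3.6e6, gt=0)
    diffusion_m2_s: float = Field(2.0e-3, gt=0)
    duration_h: float = Field(72.0, gt=0)
    well_diameter_mm: float = Field(34.8, gt=0)
    insert_diameter_mm: float = Field(24.0, gt=0)
    insert_wall_thickness_mm: float = Field(1.0, gt=0)
    bottom_chamber_height_mm: float = Field(2.0, gt=0)
    top_chamber_height_mm: float = Field(2.0, gt=0)
    nr: int = Field(64, ge=4)
    nz: int = Field(48, ge=4)
    n_steps: int = Field(400, ge=1)
    counting: Literal["cumulative_flux", "region_content"] = "cumulative_flux"

    @model_validator(mode="after")
    def _rate_for_condition(self):
        if self.condition == "custom" and self.per_cell_rate_per_h_per_1e5 is None:
            raise ValueError("custom condition requires an explicit release rate")
        return self

    def to_config(self) -> TranswellConfig:
        rate = {
            "NF": RELEASE_RATE_NF, "OF": RELEASE_RATE_OF,
            "custom": self.per_cell_rate_per_h_per_1e5,
        }[self.condition]
        if self.per_cell_rate_per_h_per_1e5 is not None:
            rate = self.per_cell_rate_per_h_per_1e5
        return TranswellConfig(
            per_cell_rate=rate,
            cell_count=self.cell_count,
            gamma=self.diffusion_m2_s,
            duration=self.duration_h * 3600.0,
            well_diameter=self.well_diameter_mm * 1e-3,
            insert_diameter=self.insert_diameter_mm * 1e-3,
            insert_wall_thickness=self.insert_wall_thickness_mm * 1e-3,
            bottom_chamber_height=self.bottom_chamber_height_mm * 1e-3,
            top_chamber_height=self.top_chamber_height_mm * 1e-3,
            nr=self.nr, nz=self.nz, n_steps=self.n_steps,
            counting_mode=self.counting,
        )


class TmeBlock(_Strict):
    stage: Literal["early", "late"] = "early"
    release_rate_per_s: float | None = Field(None, ge=0)
    inlet_velocity_um_s: float = Field(0.75, ge=0)
    diffusion_m2_s: float = Field(4.5e-12, gt=0)
    duration_min: float = Field(45.0, gt=0)
    resolution: int = Field(256, ge=4)
    scheme: Literal["upwind1", "upwind2", "quick", "muscl"] = "quick"
    domain_size_um: float = Field(1000.0, gt=0)
    tumor_radius_early_um: float = Field(100.0, gt=0)
    late_scale: float = Field(1.8, gt=1)
    n_macrophages: int = Field(10, ge=0)
    n_tcells: int = Field(15, ge=0)
    n_mdscs: int = Field(5, ge=0)
    layout_file: str | None = None

    def to_config(self, seed: int, base_dir: Path | None = None) -> TmeConfig:
        if self.layout_file is not None:
            p = Path(self.layout_file)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            layout = CellLayout.from_dict(json.loads(p.read_text()))
        else:
            L = self.domain_size_um * 1e-6
            layout = generate_tme_layout(
                stage=self.stage,
                n_macrophages=self.n_macrophages,
                n_tcells=self.n_tcells,
                n_mdscs=self.n_mdscs,
                seed=seed,
                extent=(0.0, L, 0.0, L),
                tumor_radius_early=self.tumor_radius_early_um * 1e-6,
                late_scale=self.late_scale,
            )
        rate = self.release_rate_per_s
        if rate is None:
            rate = 2.5 if self.stage == "early" else 7.5
        return TmeConfig(
            layout=layout,
            release_rate=rate,
            inlet_velocity=self.inlet_velocity_um_s * 1e-6,
            gamma=self.diffusion_m2_s,
            duration=self.duration_min * 60.0,
            resolution=self.resolution,
            scheme=self.scheme,
        )


class RunConfig(_Strict):
    """Top-level run description: scenario id plus its parameter block."""

    scenario: Literal["benchmark", "transwell", "tme"]
    seed: int = 0
    output_dir: str = "out"
    n_checkpoints: int = Field(4, ge=0)
    benchmark: BenchmarkBlock | None = None
    transwell: TranswellBlock | None = None
    tme: TmeBlock | None = None

    @model_validator(mode="after")
    def _block_matches_scenario(self):
        if getattr(self, self.scenario) is None:
            # fill the scenario block with defaults when omitted entirely
            setattr(self, self.scenario, {
                "benchmark": BenchmarkBlock,
                "transwell": TranswellBlock,
                "tme": TmeBlock,
            }[self.scenario]())
        return self

    def to_dict(self) -> dict:
        return self.model_dump(exclude_none=True)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = tomllib.loads(text)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid configuration {path}:\n{exc}") from exc


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config back out as JSON (loadable by :func:`load_config`)."""
    path = Path(path)
    path.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    return path
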