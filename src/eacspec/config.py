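"""Run configuration: schema-validated YAML loading and deterministic seeding.

A run is described by one YAML (or JSON) file covering the medium, the
perturbation list, engine settings, separations and seeds.  Validation is
strict — unknown keys are rejected and every violation is reported with its
field path — so a typo cannot silently fall back to a default.

One global seed expands into independent per-stage substreams through
``numpy.random.SeedSequence(global_seed).spawn``; stage *i* always receives
the same substream regardless of which stages actually run, so any stage can
be re-executed in isolation and reproduce its outputs bit-for-bit (for the
deterministic diffusion engine, exactly; for MC, per platform).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "MediumSection",
    "PerturbationSection",
    "MCSection",
    "NoiseSection",
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_config_echo",
    "stage_seeds",
]


class ConfigError(ValueError):
    """Configuration file invalid; message lists every offending field."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class MediumSection(_Strict):
    concentration_pct: float = Field(3.0, gt=0)
    radius_um: float = Field(0.5, gt=0)
    wavelength_start_nm: float = Field(1000.0, ge=1000.0)
    wavelength_stop_nm: float = Field(1660.0, le=1700.0)
    wavelength_step_nm: float = Field(10.0, gt=0)


class PerturbationSection(_Strict):
    kind: Literal[
        "glucose",
        "nacl",
        "particle_density",
        "particle_size",
        "intralipid_concentration",
    ]
    amount: float
    mask: Literal["both", "scattering_only", "absorption_only"] = "both"


class MCSection(_Strict):
    n_photons: int = Field(1_000_000, ge=1)
    radial_bin_dr_cm: float = Field(0.005, gt=0)
    n_radial_bins: int = Field(100, ge=1)
    weight_threshold: float = Field(1e-4, gt=0, lt=1)
    roulette_survival_inverse: int = Field(10, ge=2)
    ambient_index: float = Field(1.0, gt=0)
    n_batches: int = Field(10, ge=2)


class NoiseSection(_Strict):
    wavelengths_nm: list[float] = Field(
        default_factory=lambda: [1050.0, 1219.0, 1314.0, 1409.0, 1550.0, 1609.0]
    )
    sd: list[float] = Field(
        default_factory=lambda: [0.001, 0.002, 0.002, 0.004, 0.002, 0.003]
    )
    closer_sds_factor: float = Field(0.8, ge=0, le=1)


class RunConfig(_Strict):
    medium: MediumSection = Field(default_factory=MediumSection)
    perturbations: list[PerturbationSection] = Field(
        default_factory=lambda: [PerturbationSection(kind="glucose", amount=100.0)]
    )
    engine: Literal["diffusion", "mc"] = "diffusion"
    sds_pair_cm: tuple[float, float] = (0.08, 0.2)
    instrument_sds_cm: tuple[float, ...] = (0.125, 0.17, 0.20, 0.23)
    mc: MCSection = Field(default_factory=MCSection)
    noise: NoiseSection = Field(default_factory=NoiseSection)
    seed: int = 0
    output_dir: str = "eacspec_out"

    def wavelengths_nm(self) -> np.ndarray:
        m = self.medium
        return np.arange(
            m.wavelength_start_nm,
            m.wavelength_stop_nm + 0.5 * m.wavelength_step_nm,
            m.wavelength_step_nm,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from exc


def write_config_echo(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write the fully resolved config (defaults filled) for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = out_dir / "config_echo.yaml"
    echo.write_text(yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True))
    return echo


def stage_seeds(global_seed: int, n_stages: int = 8) -> list[int]:
    """Deterministic per-stage substream seeds (< 2**31) from one seed."""
    seqs = np.random.SeedSequence(global_seed).spawn(n_stages)
    return [int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for s in seqs]
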