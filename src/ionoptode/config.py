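"""Run configuration: schema, units, loading and write-back.

A single YAML/JSON schema drives every command. Concentrations are always
*serialized* in molar (scientific notation); on input, strings with an
explicit unit suffix ("105 nM", "1.35 uM", "1 mM") are accepted and
converted. Every run writes its fully resolved configuration next to its
outputs so results are reproducible from the artifact alone.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .optode import EquilibriumParams, OptodeComposition, exchange_constant_for_midpoint
from .synthetic import ChannelGains, NoiseSpec, TransientSpec

__all__ = [
    "ConfigError",
    "parse_concentration",
    "RunConfig",
    "load_config",
    "write_resolved_config",
]


class ConfigError(ValueError):
    """Invalid configuration file or value."""


_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9, "pm": 1e-12}
_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Zµ]+)\s*$")


def parse_concentration(value) -> float:
    """Molar concentration from a number (molar) or a unit-suffixed string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _CONC_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse concentration {value!r}")
    num, unit = m.groups()
    unit = unit.replace("µ", "u").lower()
    if unit not in _UNITS:
        raise ConfigError(f"unknown concentration unit {unit!r} in {value!r}")
    return float(num) * _UNITS[unit]


class CompositionConfig(BaseModel):
    chromoionophore_total: float = 1.0
    exchanger_total: float = 1.276
    ionophore_total: float = 2.278
    ion_charge: int = 2
    stoichiometry: int = 2

    def build(self) -> OptodeComposition:
        return OptodeComposition(**self.model_dump())


class EquilibriumConfig(BaseModel):
    """K_exch may be given directly or solved from a target midpoint."""

    ph: float = 7.2
    exchange_constant: float | None = None
    midpoint_concentration: float | str | None = "105 nM"

    @field_validator("midpoint_concentration")
    @classmethod
    def _parse_conc(cls, v):
        return None if v is None else parse_concentration(v)

    def build(self, comp: OptodeComposition) -> EquilibriumParams:
        if self.exchange_constant is not None:
            return EquilibriumParams.from_ph(self.exchange_constant, self.ph)
        if self.midpoint_concentration is None:
            raise ConfigError(
                "equilibrium needs exchange_constant or midpoint_concentration"
            )
        # defaults bypass field validation; parse here as well
        k = exchange_constant_for_midpoint(
            comp, self.ph, parse_concentration(self.midpoint_concentration)
        )
        return EquilibriumParams.from_ph(k, self.ph)


class GainsConfig(BaseModel):
    gain_sense: float = 640.0
    gain_ref: float = 800.0
    span_sense: float = 1.0
    offset_sense: float = 0.3
    span_ref: float = 0.05
    offset_ref: float = 1.0

    def build(self) -> ChannelGains:
        return ChannelGains(**self.model_dump())


class NoiseConfig(BaseModel):
    preset: Literal["paper_like", "plate_reader", "flowchamber", "noiseless", "high_snr", "low_snr", "custom"] = "paper_like"
    photon_scale: float | None = None
    read_noise_sd: float | None = None
    bleach_rate_sense: float | None = None
    bleach_rate_ref: float | None = None
    background_level: float | None = None

    def build(self, seed: int) -> NoiseSpec:
        if self.preset == "custom":
            spec = NoiseSpec(seed=seed)
        else:
            spec = getattr(NoiseSpec, self.preset)(seed)
        overrides = {
            k: v
            for k, v in self.model_dump().items()
            if k != "preset" and v is not None
        }
        if overrides:
            import dataclasses

            spec = dataclasses.replace(spec, **overrides)
        return spec


class TransientConfig(BaseModel):
    baseline: float | str = 1.0e-7
    peak: float | str = 4.0e-7
    onset: float = 60.0
    rise_tau: float = 5.0
    decay_tau: float = 120.0
    duration: float = 600.0

    @field_validator("baseline", "peak")
    @classmethod
    def _conc(cls, v):
        return parse_concentration(v)

    def build(self) -> TransientSpec:
        return TransientSpec(**self.model_dump())


class SimulateConfig(BaseModel):
    kind: Literal["calibration", "carbachol", "reversibility", "in_situ"] = "carbachol"
    frame_interval: float = 1.0
    shape: tuple[int, int] = (256, 256)
    n_cells: int = 3
    n_replicates: int = 3
    # reversibility protocol
    low: float | str = 1.0e-7
    high: float | str = 1.35e-6
    dwell: float = 120.0
    n_cycles: int = 5
    # in situ step protocol
    step_concentrations: list[float | str] | None = None
    frames_per_step: int = 5

    @field_validator("low", "high")
    @classmethod
    def _conc(cls, v):
        return parse_concentration(v)

    @field_validator("step_concentrations")
    @classmethod
    def _concs(cls, v):
        return None if v is None else [parse_concentration(x) for x in v]


class CalibrateConfig(BaseModel):
    calibration_csv: str | None = None
    endpoints_csv: str | None = None
    pooled: bool = False
    weighted: bool = False


class QuantifyConfig(BaseModel):
    stack_tiff: str | None = None
    roi_tiff: str | None = None
    roi_csv: str | None = None
    calibration_json: str | None = None
    frame_interval: float = 1.0
    stimulus_frame: int = 60
    baseline_start: int = 0
    bleach_model: Literal["exponential", "linear"] = "exponential"
    static_reference: bool = False
    peak_smooth_s: float = 20.0
    peak_search_s: float | None = None


class RunConfig(BaseModel):
    """Top-level schema; unknown keys are rejected so typos fail loudly."""

    model_config = {"extra": "forbid"}

    seed: int
    output_dir: str = "ionoptode_out"
    log_level: str = "INFO"
    composition: CompositionConfig = Field(default_factory=CompositionConfig)
    equilibrium: EquilibriumConfig = Field(default_factory=EquilibriumConfig)
    gains: GainsConfig = Field(default_factory=GainsConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    transient: TransientConfig = Field(default_factory=TransientConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    calibrate: CalibrateConfig = Field(default_factory=CalibrateConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)


def load_config(path, *, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML or JSON config; all schema violations are
    reported together (pydantic aggregates them)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if seed is not None:
        raw["seed"] = seed
    return RunConfig.model_validate(raw)


def write_resolved_config(config: RunConfig, output_dir) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "resolved_config.yaml"
    target.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
    return target
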