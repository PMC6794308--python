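"""YAML pipeline configuration with schema validation.

The config is a nested document with one section per stage.  Unknown keys
are rejected (typos must not silently fall back to defaults) and every
default is resolved at load time, so an empty file yields the full default
configuration: O₂:C ratios 2.7 and 1.1, λ = 0.518, branch-length cutoff
2.0, read-length minima 100 nt / 33 aa, export scale 2, layer 200 m,
residence time 3.9 yr, 365.25 d yr⁻¹.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["PipelineConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; message lists the offending field paths."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GasExchangeSection(_Section):
    parameterization: str = "quadratic"
    coefficient: float = Field(0.251, gt=0)  # cm h⁻¹ (m s⁻¹)⁻²
    schmidt_ref: float = Field(660.0, gt=0)
    schmidt_coeffs: list[float] = [1920.4, -135.6, 5.2122, -0.10939, 0.00093777]
    window_days: int = Field(60, ge=1)


class IsotopeSection(_Section):
    lambda_: float = Field(0.518, gt=0, lt=1, alias="lambda")
    d17_photo_per_meg: float = 249.0
    d17_eq_per_meg: float = 8.0
    delta18_eq_per_mil: float = 0.73
    natural_abundance_13c_atom_pct: float = Field(1.1, gt=0)
    model_config = ConfigDict(extra="forbid", frozen=True, populate_by_name=True)


class ConversionSection(_Section):
    gross_o2_to_net_c: float = Field(2.7, gt=0)
    ncp_o2_to_c: float = Field(1.1, gt=0)


class MonteCarloSection(_Section):
    n_draws: int = Field(1000, ge=100)
    seed: int = 0


class BudgetSection(_Section):
    export_scale: float = Field(2.0, ge=1)
    consumed_fraction: float = Field(1.0, gt=0, le=1)
    layer_thickness_m: float = Field(200.0, gt=0)
    residence_time_yr: float = Field(3.9, gt=0)
    residence_time_sigma_yr: float = Field(0.8, ge=0)
    days_per_year: float = Field(365.25, gt=0)
    anammox_pairing: bool = True
    om_formula: list[float] = [106.0, 175.0, 42.0, 16.0, 1.0]  # C H O N P


class FilterSection(_Section):
    max_branch_length: float = 2.0
    min_read_len_nt: int = 100
    min_read_len_aa: int = 33
    max_evalue_exponent: float = -5.0


class SyntheticSection(_Section):
    n_days: int = Field(60, ge=1)
    mean_wind_m_s: float = Field(7.0, ge=0)
    wind_noise: float = Field(0.25, ge=0)
    true_gpp: float = Field(60.0, ge=0)
    true_ncp: float = 3.0
    mld_m: float = Field(25.0, gt=0)
    temperature_c: float = 27.0
    salinity_psu: float = 34.5
    trap_depths_m: list[float] = [105.0, 150.0, 750.0]
    background_flux: float = Field(0.39, ge=0)
    in_situ_production: float = Field(0.27, ge=0)
    virus_host_ratio: float = Field(35.0, ge=0)
    library_size: int = Field(100_000, gt=0)
    marker_reads: int = Field(20_000, gt=0)
    contaminant_fraction: float = Field(0.012, ge=0, lt=1)
    sigma_delta17: float = Field(0.002, ge=0)
    sigma_delta18: float = Field(0.004, ge=0)
    sigma_o2ar: float = Field(0.001, ge=0)


class IOSection(_Section):
    out_dir: str = "odz_output"


class PipelineConfig(_Section):
    seed: int = 0
    gas_exchange: GasExchangeSection = GasExchangeSection()
    isotopes: IsotopeSection = IsotopeSection()
    conversions: ConversionSection = ConversionSection()
    monte_carlo: MonteCarloSection = MonteCarloSection()
    budget: BudgetSection = BudgetSection()
    filters: FilterSection = FilterSection()
    synthetic: SyntheticSection = SyntheticSection()
    io: IOSection = IOSection()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` or an empty file → defaults.

    Raises :class:`ConfigError` naming the offending key paths on any
    schema violation.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration — {paths}") from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved config back to YAML (round-trip stable)."""
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(by_alias=True), sort_keys=True)
    )
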