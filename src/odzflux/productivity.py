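"""Mixed-layer productivity from dissolved-gas tracers and ¹³C incubations.

Two incubation-free rate estimates come from a steady-state one-box model of
the mixed layer:

* **GPP from the triple oxygen isotope (TOI) excess.**  Photosynthetic O₂
  carries a higher ¹⁷Δ than O₂ equilibrated with air (stratospheric
  photochemistry depletes atmospheric O₂ in ¹⁷O mass-independently), and
  respiration, being mass-dependent, leaves ¹⁷Δ untouched.  At steady state
  the dissolved ¹⁷Δ is a mixing ratio between the air-equilibrium and
  photosynthetic end-members, so

      GPP = k·[O₂]eq·(¹⁷Δ_diss − ¹⁷Δ_eq)/(¹⁷Δ_photo − ¹⁷Δ_diss)

* **NCP from the biological O₂ supersaturation.**  Ar tracks the physical
  part of the O₂ saturation anomaly, so the O₂/Ar supersaturation Δ(O₂/Ar)
  isolates the biological part, and at steady state the biological O₂ flux
  out of the mixed layer is

      NCP = k·[O₂]eq·Δ(O₂/Ar)

Both assume steady state and negligible mixing/advection.  Uncertainties are
propagated by Monte Carlo perturbation of the measured inputs.  ¹³C-uptake
incubations give volumetric NPP (dark-corrected), which can be depth
integrated and combined with NCP into an export efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "TripleOxygenSample",
    "IsotopeConstants",
    "ConversionConstants",
    "IncubationSample",
    "ProductivityResult",
    "delta17_excess",
    "gpp_from_toi",
    "ncp_from_o2ar",
    "monte_carlo_uncertainty",
    "convert_gpp_to_npp",
    "convert_ncp_to_c",
    "npp_13c_rate",
    "integrate_profile",
    "export_efficiency",
]


@dataclass(frozen=True)
class TripleOxygenSample:
    """One station's mixed-layer dissolved-O₂ isotope and O₂/Ar state.

    δ values are per mil vs atmospheric O₂; ``o2ar_supersat`` is the
    dimensionless biological supersaturation Δ(O₂/Ar) = measured/equilibrium − 1.
    """

    station: str
    date: str
    delta17: float
    delta18: float
    o2ar_supersat: float
    sigma_delta17: float = 0.0
    sigma_delta18: float = 0.0
    sigma_o2ar: float = 0.0

    def __post_init__(self) -> None:
        if self.delta17 <= -1000 or self.delta18 <= -1000:
            raise ValueError("delta values must exceed −1000 per mil")
        if min(self.sigma_delta17, self.sigma_delta18, self.sigma_o2ar) < 0:
            raise ValueError("measurement uncertainties must be ≥ 0")


@dataclass(frozen=True)
class IsotopeConstants:
    """Triple-oxygen-isotope system constants.

    ``lambda_`` is the mass-dependent slope; end-members are ¹⁷Δ of
    photosynthetic O₂ and of air-equilibrated water, in per meg.  The
    equilibrium δ¹⁸O (per mil vs atmospheric O₂) anchors forward models.
    Defaults are standard literature values; all are configurable.
    """

    lambda_: float = 0.518
    d17_photo: float = 249.0  # per meg
    d17_eq: float = 8.0  # per meg
    delta18_eq: float = 0.73  # per mil

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ < 1.0):
            raise ValueError("lambda must lie in (0, 1)")
        if self.d17_photo <= self.d17_eq:
            raise ValueError("photosynthetic ¹⁷Δ end-member must exceed equilibrium")


@dataclass(frozen=True)
class ConversionConstants:
    """O₂↔C conversion ratios.

    2.7 mol gross O₂ per mol net C maps TOI-GPP onto incubation-style NPP;
    1.1 mol O₂ per mol C converts NCP assuming recycled-nitrogen production.
    """

    gross_o2_to_net_c: float = 2.7
    ncp_o2_to_c: float = 1.1

    def __post_init__(self) -> None:
        if self.gross_o2_to_net_c <= 0 or self.ncp_o2_to_c <= 0:
            raise ValueError("conversion ratios must be > 0")


@dataclass(frozen=True)
class IncubationSample:
    """One bottle of a ¹³C-bicarbonate uptake incubation."""

    depth: float  # m
    light: bool
    replicate: str
    pc_conc: float  # particulate C, µM
    atom_pc_t0: float  # natural-abundance atom% ¹³C of particulate pool
    atom_pc_t24: float  # atom% ¹³C of particulate pool at end
    atom_dic: float  # atom% ¹³C of dissolved pool after spike
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        for a in (self.atom_pc_t0, self.atom_pc_t24, self.atom_dic):
            if not (0.0 <= a <= 100.0):
                raise ValueError(f"atom% {a} outside 0…100")
        if self.duration_h <= 0:
            raise ValueError("incubation duration must be > 0")


@dataclass
class ProductivityResult:
    """Station-level rates with Monte Carlo uncertainties."""

    station: str
    gpp_o2: float
    gpp_o2_se: float
    ncp_o2: float
    ncp_o2_se: float
    npp_c: float
    npp_c_se: float
    ncp_c: float
    ncp_c_se: float
    n_draws: int
    seed: int


def delta17_excess(
    delta17: float, delta18: float, consts: IsotopeConstants | None = None
) -> float:
    """¹⁷Δ (per meg) from δ¹⁷O and δ¹⁸O (per mil).

    ¹⁷Δ = [ln(1+δ¹⁷O/1000) − λ·ln(1+δ¹⁸O/1000)]·10⁶ — the deviation of δ¹⁷O
    from the mass-dependent expectation, insensitive to respiration.
    """
    consts = consts or IsotopeConstants()
    if delta17 <= -1000 or delta18 <= -1000:
        raise ValueError("delta values must exceed −1000 per mil")
    return (
        math.log1p(delta17 / 1000.0) - consts.lambda_ * math.log1p(delta18 / 1000.0)
    ) * 1e6


def gpp_from_toi(
    sample: TripleOxygenSample,
    k: float,
    o2eq: float,
    consts: IsotopeConstants | None = None,
) -> float:
    """Mixed-layer GPP (mmol O₂ m⁻² d⁻¹) from the steady-state TOI balance.

    Raises if the dissolved ¹⁷Δ reaches the photosynthetic end-member (the
    steady-state expression diverges there — pure photosynthetic O₂ implies
    no air–sea exchange constraint).
    """
    consts = consts or IsotopeConstants()
    d17_diss = delta17_excess(sample.delta17, sample.delta18, consts)
    if d17_diss >= consts.d17_photo:
        raise ValueError(
            f"dissolved ¹⁷Δ {d17_diss:.1f} per meg ≥ photosynthetic end-member "
            f"{consts.d17_photo}; steady-state GPP undefined"
        )
    return k * o2eq * (d17_diss - consts.d17_eq) / (consts.d17_photo - d17_diss)


def ncp_from_o2ar(sample: TripleOxygenSample, k: float, o2eq: float) -> float:
    """NCP (mmol O₂ m⁻² d⁻¹) from biological O₂/Ar supersaturation.

    Negative supersaturation yields negative NCP (net heterotrophy); the sign
    is preserved.
    """
    if sample.o2ar_supersat <= -1.0:
        raise ValueError("O₂/Ar supersaturation must exceed −1")
    return k * o2eq * sample.o2ar_supersat


def monte_carlo_uncertainty(
    fn: Callable[..., float],
    inputs: Mapping[str, tuple[float, float]],
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Propagate stated 1σ input uncertainties through ``fn`` by Monte Carlo.

    ``inputs`` maps keyword names to ``(value, sigma)``; each draw perturbs
    every input with independent Gaussian noise and re-evaluates ``fn``.
    Returns ``(mean, sd)`` of the draws.  Reproducible for a fixed seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be ≥ 100 for a stable SD estimate")
    for name, (_, sigma) in inputs.items():
        if sigma < 0:
            raise ValueError(f"negative sigma for input {name!r}")
    rng = np.random.default_rng(seed)
    names = list(inputs)
    values = np.array([inputs[n][0] for n in names])
    sigmas = np.array([inputs[n][1] for n in names])
    draws = np.empty(n_draws)
    for i in range(n_draws):
        perturbed = values + rng.standard_normal(len(names)) * sigmas
        draws[i] = fn(**dict(zip(names, perturbed)))
    return float(draws.mean()), float(draws.std(ddof=1))


def convert_gpp_to_npp(gpp_o2: float, consts: ConversionConstants | None = None) -> float:
    """Convert TOI-GPP (mmol O₂ m⁻² d⁻¹) to NPP-equivalent mmol C m⁻² d⁻¹."""
    consts = consts or ConversionConstants()
    return gpp_o2 / consts.gross_o2_to_net_c


def convert_ncp_to_c(ncp_o2: float, consts: ConversionConstants | None = None) -> float:
    """Convert NCP from O₂ to C units (recycled-N production ratio)."""
    consts = consts or ConversionConstants()
    return ncp_o2 / consts.ncp_o2_to_c


def npp_13c_rate(
    samples: Sequence[IncubationSample], floor_at_zero: bool = False
) -> float:
    """Dark-corrected volumetric carbon-fixation rate (µM C d⁻¹).

    Per bottle, rate = [(atom%_PC,final − atom%_PC,natural) /
    (atom%_DIC − atom%_PC,natural)]·[PC]/Δt; the mean dark rate is
    subtracted from the mean light rate.  Negative net rates are reported
    unless ``floor_at_zero``.
    """
    light = [s for s in samples if s.light]
    dark = [s for s in samples if not s.light]
    if not light or not dark:
        raise ValueError("need at least one light and one dark bottle")

    def bottle_rate(s: IncubationSample) -> float:
        denom = s.atom_dic - s.atom_pc_t0
        if denom <= 0:
            raise ValueError(
                "dissolved-pool enrichment must exceed natural particulate abundance"
            )
        days = s.duration_h / 24.0
        return (s.atom_pc_t24 - s.atom_pc_t0) / denom * s.pc_conc / days

    rate = float(np.mean([bottle_rate(s) for s in light])) - float(
        np.mean([bottle_rate(s) for s in dark])
    )
    return max(rate, 0.0) if floor_at_zero else rate


def integrate_profile(
    depths: Sequence[float],
    rates: Sequence[float],
    z_top: float,
    z_bottom: float,
) -> float:
    """Trapezoid-integrate a volumetric rate profile over [z_top, z_bottom].

    µM·m ≡ mmol m⁻²; interior bounds are handled by linear interpolation,
    but extrapolation beyond the sampled depths is refused.
    """
    depths = np.asarray(depths, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(depths) < 2 or np.any(np.diff(depths) <= 0):
        raise ValueError("need ≥ 2 strictly increasing depths")
    if z_top < depths[0] or z_bottom > depths[-1] or z_top >= z_bottom:
        raise ValueError(
            f"bounds [{z_top}, {z_bottom}] must lie within sampled depths "
            f"[{depths[0]}, {depths[-1]}]"
        )
    grid = np.unique(np.concatenate((depths, [z_top, z_bottom])))
    grid = grid[(grid >= z_top) & (grid <= z_bottom)]
    vals = np.interp(grid, depths, rates)
    return float(np.trapezoid(vals, grid))


def export_efficiency(ncp_c: float, npp_c: float) -> float:
    """NCP as a percentage of NPP (export efficiency)."""
    if npp_c <= 0:
        raise ValueError("NPP must be > 0 to define an export efficiency")
    return ncp_c / npp_c * 100.0
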