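"""Air–sea gas exchange: O₂ solubility, Schmidt number, and piston velocity.

The mixed-layer oxygen budget that underpins both the triple-oxygen-isotope
GPP estimate and the O₂/Ar NCP estimate needs three physical quantities:

* the equilibrium (saturation) O₂ concentration of seawater,
* the Schmidt number of O₂, which rescales wind-speed gas-transfer
  parameterizations between gases, and
* the gas-transfer (piston) velocity ``k``.

Because mixed-layer gas signatures integrate over days to weeks of wind
history rather than the instant of sampling, the piston velocity applied to
a station is a history-weighted average: each prior day's ``k`` is weighted
by the probability that the mixed layer had not yet been flushed between
that day and sampling (Reuer-style weighting).

All public outputs are in m d⁻¹ (velocities) and mmol m⁻³ (concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WindRecord",
    "HydroState",
    "GasExchangeParams",
    "schmidt_number",
    "piston_velocity",
    "weighted_piston_velocity",
    "o2_saturation",
]

#: cm h⁻¹ → m d⁻¹
CM_PER_HR_TO_M_PER_DAY = 24.0 / 100.0

#: ml(STP) O₂ per mmol
ML_PER_MMOL = 22.3916

# Schmidt number of O₂ in seawater (S=35), 4th-order polynomial in t (°C),
# valid −2…40 °C (Wanninkhof-2014-style fit).
SCHMIDT_O2_SEAWATER = (1920.4, -135.6, 5.2122, -0.10939, 0.00093777)

# Garcia & Gordon (1992) O₂ solubility fit, Benson & Krause data,
# ml(STP) L⁻¹; scaled temperature Ts = ln[(298.15−t)/(273.15+t)].
GG92_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
GG92_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
GG92_C0 = -4.88682e-7


@dataclass(frozen=True)
class WindRecord:
    """One day of 10 m wind speed."""

    date: str
    u10: float  # m s⁻¹

    def __post_init__(self) -> None:
        if self.u10 < 0:
            raise ValueError(f"negative wind speed: {self.u10}")


@dataclass(frozen=True)
class HydroState:
    """Mixed-layer hydrography at a station."""

    temperature: float  # °C
    salinity: float  # PSU
    mld: float  # mixed-layer depth, m

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(f"temperature {self.temperature} °C outside −2…40 °C")
        if not (0.0 <= self.salinity <= 42.0):
            raise ValueError(f"salinity {self.salinity} outside 0…42")
        if self.mld <= 0:
            raise ValueError(f"mixed-layer depth must be positive, got {self.mld}")


@dataclass(frozen=True)
class GasExchangeParams:
    """Wind-speed gas-transfer parameterization and weighting settings.

    ``coefficient`` is the quadratic coefficient in cm h⁻¹ (m s⁻¹)⁻²;
    the default 0.251 is the standard modern value.  ``schmidt_coeffs``
    is the polynomial for Sc(t); ``window`` is how many days of wind
    history enter the weighted piston velocity.
    """

    name: str = "quadratic"
    coefficient: float = 0.251
    schmidt_ref: float = 660.0
    schmidt_coeffs: tuple[float, ...] = SCHMIDT_O2_SEAWATER
    window: int = 60

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("gas-transfer coefficient must be > 0")
        if self.window < 1:
            raise ValueError("weighting window must be ≥ 1 day")


def schmidt_number(hydro: HydroState, params: GasExchangeParams | None = None) -> float:
    """Schmidt number of O₂ at the station's temperature.

    Evaluates the configured polynomial in temperature.  The default fit is
    for seawater, so salinity enters only through the choice of coefficients.
    """
    params = params or GasExchangeParams()
    t = hydro.temperature
    return float(sum(c * t**i for i, c in enumerate(params.schmidt_coeffs)))


def piston_velocity(
    u10: float, hydro: HydroState, params: GasExchangeParams | None = None
) -> float:
    """Instantaneous piston velocity k (m d⁻¹) from a quadratic wind-speed law.

    k = a·u10²·(Sc/Sc_ref)^(−1/2), with a in cm h⁻¹ (m s⁻¹)⁻², converted
    to m d⁻¹.
    """
    if u10 < 0:
        raise ValueError(f"negative wind speed: {u10}")
    params = params or GasExchangeParams()
    sc = schmidt_number(hydro, params)
    k_cm_hr = params.coefficient * u10**2 * (sc / params.schmidt_ref) ** -0.5
    return k_cm_hr * CM_PER_HR_TO_M_PER_DAY


def weighted_piston_velocity(
    history: Sequence[WindRecord],
    hydro: HydroState,
    params: GasExchangeParams | None = None,
) -> tuple[float, np.ndarray]:
    """Mixed-layer-history-weighted piston velocity.

    Walking backwards from the sampling day (the last record), day *i*
    ventilates a fraction f_i = min(1, k_i·Δt/z_ml) of the mixed layer; its
    weight is the fraction it ventilates of whatever earlier days have not
    already flushed: ω_i = f_i·∏_{j<i}(1−f_j).  Weights are renormalized to
    sum to 1 and k_w = Σ ω_i k_i.

    Returns ``(k_w, weights)`` with weights in the same (chronological)
    order as ``history``.
    """
    if len(history) == 0:
        raise ValueError("wind history is empty")
    params = params or GasExchangeParams()
    window = min(params.window, len(history))
    recent = history[-window:]  # chronological; last entry = sampling day

    ks = np.array([piston_velocity(rec.u10, hydro, params) for rec in recent])
    # iterate backwards in time from the sampling day
    f = np.minimum(1.0, ks[::-1] / hydro.mld)  # Δt = 1 day
    survive = np.concatenate(([1.0], np.cumprod(1.0 - f)[:-1]))
    omega_back = f * survive
    total = omega_back.sum()
    if total == 0.0:
        # calm window: no ventilation at all → uniform weights, k_w = mean k
        omega_back = np.full_like(omega_back, 1.0 / len(omega_back))
    else:
        omega_back = omega_back / total
    weights = omega_back[::-1]  # back to chronological order
    k_w = float(np.dot(weights, ks))
    return k_w, weights


def o2_saturation(hydro: HydroState) -> float:
    """Equilibrium O₂ concentration (mmol m⁻³) at the station's T and S.

    Garcia & Gordon (1992) combined fit to the Benson & Krause solubility
    data, evaluated in ml(STP) L⁻¹ and converted with 22.3916 ml mmol⁻¹.
    """
    t, s = hydro.temperature, hydro.salinity
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = sum(a * ts**i for i, a in enumerate(GG92_A))
    ln_c += s * sum(b * ts**i for i, b in enumerate(GG92_B))
    ln_c += GG92_C0 * s**2
    ml_per_l = math.exp(ln_c)
    return ml_per_l / ML_PER_MMOL * 1000.0
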