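import pytest

from odzflux import GasExchangeParams, HydroState, ScenarioConfig


@pytest.fixture
def hydro():
    """Warm oligotrophic mixed layer (27 °C, 34.5 PSU, 25 m)."""
    return HydroState(temperature=27.0, salinity=34.5, mld=25.0)


@pytest.fixture
def flat_schmidt():
    """Parameterization with Sc pinned to the reference value, so the
    Schmidt correction drops out and k = 0.24·a·u10² m d⁻¹ exactly."""
    return GasExchangeParams(schmidt_coeffs=(660.0,))


@pytest.fixture
def noise_free_scenario():
    return ScenarioConfig(
        seed=7,
        sigma_delta17=0.0,
        sigma_delta18=0.0,
        sigma_o2ar=0.0,
        flux_noise=0.0,
        contaminant_fraction=0.0,
    )
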