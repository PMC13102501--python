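import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import otofmr as o

# deterministic property tests, no on-disk example database
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_scenario():
    """Default five-species, two-location scenario with matching config."""
    species, locations = o.default_params()
    cfg = o.simulation_config(locations, species)
    return species, locations, cfg


@pytest.fixture(scope="session")
def derived_default(default_scenario):
    """A derived default cohort (seeded) shared by read-only tests."""
    species, locations, cfg = default_scenario
    samples, truth = o.simulate_cohort(species, locations, seed=20191001, n_per_cell=60)
    derived, report = o.derive_all(samples, cfg)
    return derived, truth, cfg, report


@pytest.fixture()
def plain_config():
    """Config with synthetic cubic length-weight coefficients for species X/Y."""
    return o.EnvCalibConfig(
        lw_coeffs={"X": (0.01, 3.0), "Y": (0.01, 3.0)},
        large_thresholds={"X": 0.0, "Y": 0.0},
    )


def make_scaling_frame(
    alpha, e_ev, b0=70.0, anchor_mass=10.0, anchor_temp=13.0,
    masses=None, temps=None, config=None, species="X", location="Dorset",
):
    """Noise-free data generated exactly from the anchored scaling law."""
    cfg = config or o.EnvCalibConfig()
    masses = np.asarray(
        masses if masses is not None else np.geomspace(2, 50, 25), dtype=float
    )
    if temps is None:
        temps = 16.0 - 2.5 * np.log10(masses)
    temps = np.asarray(temps, dtype=float)
    d_inv = o.inverse_temperature(temps, cfg) - o.inverse_temperature(anchor_temp, cfg)
    fmr = b0 * (masses / anchor_mass) ** alpha * np.exp(e_ev * d_inv)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(masses))],
            "species": species,
            "location": location,
            "body_mass_g": masses,
            "temperature_C": temps,
            "fmr_mgO2_kg_hr": fmr,
        }
    )
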