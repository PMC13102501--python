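"""Environmental and calibration constants for the isotope proxies.

The proxy equations need a small set of constants: the oxygen-isotope
composition of seawater at each sampling location (per-mil VPDB), the
carbon-isotope composition of dissolved inorganic carbon (DIC), the
aragonite temperature-fractionation coefficients, the linear calibration
converting the respired-carbon fraction ``C_resp`` to mass-specific oxygen
consumption, species length-weight coefficients, and the size thresholds
used to define "large" individuals and conservation reference sizes (CRS).

:class:`EnvCalibConfig` bundles all of them, validates the physical
invariants, and round-trips to a flat sectioned YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

from .exceptions import ConfigurationError

#: Boltzmann's constant in eV K^-1, as used in Arrhenius inverse temperature.
BOLTZMANN_EV = 8.62e-5

#: Offset from degrees Celsius to Kelvin.
KELVIN_OFFSET = 273.15

#: The five wrasse species sampled at both study locations.
WRASSE_SPECIES = (
    "C. exoletus",
    "C. rupestris",
    "L. bergylta",
    "L. mixtus",
    "S. melops",
)

#: Large-individual body-mass thresholds (g) per species, used as the floor
#: when subsetting for the location model of FMR.
LARGE_THRESHOLD_G = {
    "C. exoletus": 20.0,
    "C. rupestris": 30.0,
    "L. bergylta": 300.0,
    "L. mixtus": 150.0,
    "S. melops": 75.0,
}

#: Minimum / maximum conservation reference sizes (total length, cm).
#: Only the ballan wrasse limits for the Dorset district are bundled.
CRS_LIMITS_CM = {
    "L. bergylta": (18.0, 28.0),
}


@dataclass
class EnvCalibConfig:
    """Water, fractionation, calibration and threshold constants.

    Parameters
    ----------
    d18o_sw
        Seawater oxygen-isotope composition per location (per-mil VPDB).
    d13c_dic
        Seawater DIC carbon-isotope composition (per-mil VPDB). One value
        shared across locations; the North Sea observation (1 per-mil) is
        the default.
    frac_a, frac_b_mag
        Intercept (per-mil) and slope magnitude (per-mil per degree C) of
        the linear aragonite-water oxygen fractionation relationship for
        saltwater fish. The slope is stored as a positive magnitude; otolith
        d18O decreases as temperature increases.
    epsilon
        Net isotopic fractionation from carbon sources to otolith
        carbonate, added outside the mass-balance ratio. Zero by default.
    c0, c1
        Intercept and slope of the linear calibration from C_resp to
        mass-specific oxygen consumption (the Atlantic-cod calibration):
        ``FMR = (C_resp - c0) / c1`` in mgO2 kg^-1 hr^-1.
    lw_coeffs
        Per-species length-weight coefficients ``(a, b)`` for
        ``W[g] = a * L[cm]**b``. No real-species defaults are bundled; the
        synthetic scenario ships ``a=0.01, b=3``.
    large_thresholds
        Per-species body-mass floors (g) defining the large-individual
        subset for the location model.
    crs_limits_cm
        Per-species (min, max) conservation reference sizes in cm.
    impute_by_location_first
        If True, diet d13C imputation averages within (species, location)
        before falling back to the species-wide mean.
    """

    d18o_sw: Dict[str, float] = field(
        default_factory=lambda: {"Dorset": 0.5, "Skye": 0.3}
    )
    d13c_dic: float = 1.0
    frac_a: float = 3.465
    frac_b_mag: float = 0.209
    epsilon: float = 0.0
    c0: float = 0.041
    c1: float = 0.000971
    lw_coeffs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    large_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(LARGE_THRESHOLD_G)
    )
    crs_limits_cm: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in CRS_LIMITS_CM.items()}
    )
    impute_by_location_first: bool = True
    boltzmann_k: float = BOLTZMANN_EV
    kelvin_offset: float = KELVIN_OFFSET

    def __post_init__(self) -> None:
        if self.frac_b_mag <= 0:
            raise ConfigurationError(
                "fractionation slope magnitude must be positive "
                f"(got {self.frac_b_mag})"
            )
        if self.c1 <= 0:
            raise ConfigurationError(f"calibration slope c1 must be positive (got {self.c1})")
        if abs(self.epsilon) >= 1:
            raise ConfigurationError(
                f"epsilon magnitude must be < 1 per-mil fraction scale (got {self.epsilon})"
            )
        self.lw_coeffs = {k: (float(v[0]), float(v[1])) for k, v in self.lw_coeffs.items()}
        self.crs_limits_cm = {
            k: (float(v[0]), float(v[1])) for k, v in self.crs_limits_cm.items()
        }

    # -- lookups ---------------------------------------------------------

    def d18o_sw_for(self, location: str) -> float:
        try:
            return self.d18o_sw[location]
        except KeyError:
            raise ConfigurationError(
                f"no seawater d18O value configured for location {location!r}"
            ) from None

    def lw(self, species: str) -> Tuple[float, float]:
        try:
            return self.lw_coeffs[species]
        except KeyError:
            raise ConfigurationError(
                f"no length-weight coefficients configured for species {species!r}"
            ) from None

    def large_threshold(self, species: str) -> float:
        try:
            return self.large_thresholds[species]
        except KeyError:
            raise ConfigurationError(
                f"no large-individual threshold configured for species {species!r}"
            ) from None

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        """Sectioned plain-dict form used for the YAML template."""
        return {
            "water": {
                "d18O_sw": dict(self.d18o_sw),
                "d13C_DIC": self.d13c_dic,
            },
            "fractionation": {
                "a": self.frac_a,
                "b_magnitude": self.frac_b_mag,
                "epsilon": self.epsilon,
            },
            "calibration": {"c0": self.c0, "c1": self.c1},
            "constants": {
                "boltzmann_k_eV": self.boltzmann_k,
                "kelvin_offset": self.kelvin_offset,
            },
            "length_weight": {
                sp: {"a": a, "b": b} for sp, (a, b) in self.lw_coeffs.items()
            },
            "thresholds": {
                "large_individual_g": dict(self.large_thresholds),
                "crs_cm": {sp: list(v) for sp, v in self.crs_limits_cm.items()},
            },
            "options": {"impute_by_location_first": self.impute_by_location_first},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvCalibConfig":
        water = d.get("water", {})
        frac = d.get("fractionation", {})
        cal = d.get("calibration", {})
        const = d.get("constants", {})
        lw = d.get("length_weight", {}) or {}
        thr = d.get("thresholds", {}) or {}
        opts = d.get("options", {}) or {}
        kwargs = {}
        if "d18O_sw" in water:
            kwargs["d18o_sw"] = {k: float(v) for k, v in water["d18O_sw"].items()}
        if "d13C_DIC" in water:
            kwargs["d13c_dic"] = float(water["d13C_DIC"])
        if "a" in frac:
            kwargs["frac_a"] = float(frac["a"])
        if "b_magnitude" in frac:
            kwargs["frac_b_mag"] = float(frac["b_magnitude"])
        if "epsilon" in frac:
            kwargs["epsilon"] = float(frac["epsilon"])
        if "c0" in cal:
            kwargs["c0"] = float(cal["c0"])
        if "c1" in cal:
            kwargs["c1"] = float(cal["c1"])
        if "boltzmann_k_eV" in const:
            kwargs["boltzmann_k"] = float(const["boltzmann_k_eV"])
        if "kelvin_offset" in const:
            kwargs["kelvin_offset"] = float(const["kelvin_offset"])
        if lw:
            kwargs["lw_coeffs"] = {
                sp: (float(v["a"]), float(v["b"])) for sp, v in lw.items()
            }
        if "large_individual_g" in thr:
            kwargs["large_thresholds"] = {
                k: float(v) for k, v in thr["large_individual_g"].items()
            }
        if "crs_cm" in thr:
            kwargs["crs_limits_cm"] = {
                k: (float(v[0]), float(v[1])) for k, v in thr["crs_cm"].items()
            }
        if "impute_by_location_first" in opts:
            kwargs["impute_by_location_first"] = bool(opts["impute_by_location_first"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EnvCalibConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
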