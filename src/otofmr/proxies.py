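"""Isotope-to-physiology proxy conversions.

Three proxy relationships turn raw otolith isotope measurements into
per-fish physiological quantities:

* **Thermometry** — otolith aragonite forms near oxygen-isotope
  equilibrium with ambient water, so experienced temperature follows from
  the otolith-water d18O offset through a linear fractionation
  relationship: ``T = (a - (d18O_oto - d18O_sw)) / b`` with the slope
  ``b`` stored as a positive magnitude (warmer water, lighter otolith).
* **Respiration proxy** — blood (and hence otolith) carbon is a mixture
  of dietary respired carbon and seawater DIC with widely separated d13C
  end-members, so the respired fraction follows from isotopic mass
  balance: ``C_resp = (d13C_oto - d13C_DIC) / (d13C_diet - d13C_DIC) + eps``.
* **Field metabolic rate** — C_resp converts to mass-specific oxygen
  consumption through a linear calibration:
  ``FMR = (C_resp - c0) / c1``  (mgO2 kg^-1 hr^-1).

Each conversion has an exact inverse (used by the cohort simulator), and
:func:`derive_all` applies the whole chain to a sample table with
per-record provenance flags.

All scalar functions accept numpy arrays and broadcast.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .config import EnvCalibConfig
from .exceptions import ComputationError, ConfigurationError, DataError

__all__ = [
    "mass_from_length",
    "length_from_mass",
    "temperature_from_d18o",
    "d18o_from_temperature",
    "cresp_from_isotopes",
    "d13c_from_cresp",
    "fmr_from_cresp",
    "cresp_from_fmr",
    "inverse_temperature",
    "impute_diet_d13c",
    "derive_all",
]

#: Canonical raw input columns for a sample table.
RAW_COLUMNS = [
    "sample_id",
    "species",
    "location",
    "total_length_cm",
    "body_mass_g",
    "d18O_oto",
    "d13C_oto",
    "d13C_diet",
]


def mass_from_length(total_length, species: str, config: EnvCalibConfig):
    """Body mass (g) from total length (cm) via ``W = a * L**b``."""
    a, b = config.lw(species)
    length = np.asarray(total_length, dtype=float)
    if np.any(length <= 0):
        raise ComputationError("total length must be positive")
    out = a * length**b
    return float(out) if np.isscalar(total_length) else out


def length_from_mass(body_mass, species: str, config: EnvCalibConfig):
    """Inverse length-weight relationship, ``L = (W / a)**(1/b)``."""
    a, b = config.lw(species)
    mass = np.asarray(body_mass, dtype=float)
    if np.any(mass <= 0):
        raise ComputationError("body mass must be positive")
    out = (mass / a) ** (1.0 / b)
    return float(out) if np.isscalar(body_mass) else out


def temperature_from_d18o(d18o_oto, location: str, config: EnvCalibConfig):
    """Experienced temperature (deg C) from otolith d18O.

    ``T = (a - (d18O_oto - d18O_sw)) / b`` with ``b`` the positive slope
    magnitude; strictly decreasing in otolith d18O.
    """
    sw = config.d18o_sw_for(location)
    oto = np.asarray(d18o_oto, dtype=float)
    out = (config.frac_a - (oto - sw)) / config.frac_b_mag
    return float(out) if np.isscalar(d18o_oto) else out


def d18o_from_temperature(temperature_c, location: str, config: EnvCalibConfig):
    """Exact inverse of :func:`temperature_from_d18o` (simulator plumbing)."""
    sw = config.d18o_sw_for(location)
    t = np.asarray(temperature_c, dtype=float)
    out = sw + config.frac_a - config.frac_b_mag * t
    return float(out) if np.isscalar(temperature_c) else out


def cresp_from_isotopes(d13c_oto, d13c_diet, config: EnvCalibConfig):
    """Respired-carbon fraction from the two-end-member mass balance.

    With epsilon = 0 and otolith d13C a convex combination of the DIC and
    diet end-members with weight w on diet, returns exactly w.
    """
    oto = np.asarray(d13c_oto, dtype=float)
    diet = np.asarray(d13c_diet, dtype=float)
    denom = diet - config.d13c_dic
    if np.any(denom == 0):
        raise ComputationError(
            "diet d13C equals DIC d13C; the mass balance is undefined"
        )
    out = (oto - config.d13c_dic) / denom + config.epsilon
    if np.isscalar(d13c_oto) and np.isscalar(d13c_diet):
        return float(out)
    return out


def d13c_from_cresp(c_resp, d13c_diet, config: EnvCalibConfig):
    """Exact inverse of :func:`cresp_from_isotopes` (simulator plumbing)."""
    c = np.asarray(c_resp, dtype=float)
    diet = np.asarray(d13c_diet, dtype=float)
    out = config.d13c_dic + (c - config.epsilon) * (diet - config.d13c_dic)
    if np.isscalar(c_resp) and np.isscalar(d13c_diet):
        return float(out)
    return out


def fmr_from_cresp(c_resp, config: EnvCalibConfig):
    """Mass-specific FMR (mgO2 kg^-1 hr^-1): ``(C_resp - c0) / c1``."""
    c = np.asarray(c_resp, dtype=float)
    out = (c - config.c0) / config.c1
    return float(out) if np.isscalar(c_resp) else out


def cresp_from_fmr(fmr, config: EnvCalibConfig):
    """Exact inverse of :func:`fmr_from_cresp`: ``c0 + c1 * FMR``."""
    f = np.asarray(fmr, dtype=float)
    out = config.c0 + config.c1 * f
    return float(out) if np.isscalar(fmr) else out


def inverse_temperature(temperature_c, config: EnvCalibConfig):
    """Arrhenius inverse temperature ``1 / (k * T_Kelvin)`` in eV^-1."""
    t = np.asarray(temperature_c, dtype=float)
    out = 1.0 / (config.boltzmann_k * (t + config.kelvin_offset))
    return float(out) if np.isscalar(temperature_c) else out


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------


def impute_diet_d13c(
    samples: pd.DataFrame, config: EnvCalibConfig
) -> Tuple[pd.DataFrame, pd.Series]:
    """Fill missing diet d13C values from group means.

    Missing values are replaced by the arithmetic mean of the non-missing
    values within (species, location) when ``config.impute_by_location_first``
    and that group has any, otherwise by the species-wide mean. A species
    that needs imputation but has no non-missing diet value anywhere raises
    :class:`DataError` naming the species.

    Returns the table (copy) and a boolean mask of imputed records.
    """
    out = samples.copy()
    if "d13C_diet" not in out.columns:
        out["d13C_diet"] = np.nan
    diet = pd.to_numeric(out["d13C_diet"], errors="coerce")
    missing = diet.isna()
    imputed = pd.Series(False, index=out.index)
    if not missing.any():
        out["d13C_diet"] = diet
        return out, imputed

    species_mean = diet.groupby(out["species"]).mean()
    for sp in out.loc[missing, "species"].unique():
        if sp not in species_mean.index or np.isnan(species_mean[sp]):
            raise DataError(
                f"species {sp!r} has no non-missing diet d13C value to impute from"
            )

    if config.impute_by_location_first:
        group_mean = diet.groupby([out["species"], out["location"]]).mean()
        fill = pd.MultiIndex.from_frame(out[["species", "location"]]).map(group_mean)
        fill = pd.Series(np.asarray(fill, dtype=float), index=out.index)
        fill = fill.fillna(out["species"].map(species_mean))
    else:
        fill = out["species"].map(species_mean)

    diet = diet.where(~missing, fill)
    out["d13C_diet"] = diet
    imputed = missing
    return out, imputed


def derive_all(
    samples: pd.DataFrame, config: EnvCalibConfig
) -> Tuple[pd.DataFrame, dict]:
    """Derive temperature, C_resp and FMR for every record.

    Adds columns ``body_mass_g`` (filled from length where absent),
    ``temperature_C``, ``c_resp``, ``fmr_mgO2_kg_hr`` and the provenance
    flags ``flag_diet_imputed``, ``flag_cresp_out_of_range``,
    ``flag_fmr_negative``, ``flag_rejected`` and ``reject_reason``.

    A record with neither body mass nor usable total length is rejected;
    a record missing an isotope value keeps NaN in the affected derived
    column and carries the reason, while other records are processed.
    Structural problems (missing columns, unconfigured locations) raise.

    Returns the derived table and a tally report dict.
    """
    out = samples.copy()
    n_in = len(out)
    for col in ("sample_id", "species", "location"):
        if col not in out.columns:
            raise DataError(f"input table is missing required column {col!r}")
    for col in ("total_length_cm", "body_mass_g", "d18O_oto", "d13C_oto", "d13C_diet"):
        if col not in out.columns:
            out[col] = np.nan
        out[col] = pd.to_numeric(out[col], errors="coerce")

    # structural check: every referenced location must have a d18O_sw entry
    for loc in out["location"].unique():
        config.d18o_sw_for(str(loc))

    reasons = pd.Series("", index=out.index, dtype=object)

    def add_reason(mask, text):
        reasons[mask] = np.where(
            reasons[mask] == "", text, reasons[mask] + "; " + text
        )

    # body mass: measured mass wins, else converted from length
    mass = out["body_mass_g"].copy()
    need_lw = mass.isna() & out["total_length_cm"].notna() & (out["total_length_cm"] > 0)
    for sp in out.loc[need_lw, "species"].unique():
        sel = need_lw & (out["species"] == sp)
        try:
            mass[sel] = mass_from_length(out.loc[sel, "total_length_cm"].to_numpy(), sp, config)
        except ConfigurationError:
            add_reason(sel, f"no length-weight coefficients for species {sp!r}")
    no_mass = mass.isna() | (mass <= 0)
    add_reason(no_mass, "no usable body mass or total length")
    out["body_mass_g"] = mass

    # temperature
    temp = pd.Series(np.nan, index=out.index)
    has_o = out["d18O_oto"].notna()
    for loc in out["location"].unique():
        sel = has_o & (out["location"] == loc)
        if sel.any():
            temp[sel] = temperature_from_d18o(
                out.loc[sel, "d18O_oto"].to_numpy(), str(loc), config
            )
    add_reason(~has_o, "missing d18O_oto")
    out["temperature_C"] = temp

    # diet imputation, then C_resp and FMR
    has_c = out["d13C_oto"].notna()
    out, imputed = impute_diet_d13c(out, config)
    diet = out["d13C_diet"]
    cresp = pd.Series(np.nan, index=out.index)
    ok = has_c & diet.notna() & (diet != config.d13c_dic)
    if ok.any():
        cresp[ok] = cresp_from_isotopes(
            out.loc[ok, "d13C_oto"].to_numpy(), diet[ok].to_numpy(), config
        )
    add_reason(~has_c, "missing d13C_oto")
    add_reason(has_c & diet.isna(), "missing diet d13C")
    add_reason(has_c & (diet == config.d13c_dic), "diet d13C equals DIC")
    out["c_resp"] = cresp
    out["fmr_mgO2_kg_hr"] = fmr_from_cresp(cresp.to_numpy(), config)
    out.loc[cresp.isna(), "fmr_mgO2_kg_hr"] = np.nan

    out["flag_diet_imputed"] = imputed & has_c
    out["flag_cresp_out_of_range"] = cresp.notna() & ((cresp < 0) | (cresp > 1))
    out["flag_fmr_negative"] = out["fmr_mgO2_kg_hr"].notna() & (
        out["fmr_mgO2_kg_hr"] < 0
    )
    out["flag_rejected"] = no_mass
    out["reject_reason"] = reasons

    incomplete = (reasons != "") & ~no_mass
    report = {
        "n_input": int(n_in),
        "n_rejected": int(no_mass.sum()),
        "n_incomplete": int(incomplete.sum()),
        "n_diet_imputed": int(out["flag_diet_imputed"].sum()),
        "n_cresp_out_of_range": int(out["flag_cresp_out_of_range"].sum()),
        "n_fmr_negative": int(out["flag_fmr_negative"].sum()),
        "n_complete": int(n_in - no_mass.sum() - incomplete.sum()),
    }
    return out, report
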