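"""Ontogenetic thermal-niche model.

Within a single sampling location, otolith-derived experienced temperature
is regressed on log10(body mass) with species and the mass-by-species
interaction as predictors (ordinary least squares). The fitted model
describes, per species, the ontogenetic descent from warm shallow nursery
habitat into cooler adult habitat; pairwise species differences at a
common body mass are tested with Tukey-adjusted contrasts
(studentized-range family-wise adjustment); and the experienced-temperature
overlap between fish below the minimum and above the maximum conservation
reference size (CRS) summarises how strongly size limits separate thermal
habitats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import EnvCalibConfig
from .exceptions import DataError, FitError
from .proxies import mass_from_length

__all__ = ["ThermalOntogenyModel", "ThermalOntogenyResults", "crs_band_summary"]


def _design(
    log10_mass: np.ndarray, species: Sequence[str], levels: Sequence[str]
) -> pd.DataFrame:
    """Full-interaction design matrix with the first level as reference."""
    cols = {"Intercept": np.ones(len(log10_mass)), "log10_mass": log10_mass}
    species = np.asarray(species)
    for sp in levels[1:]:
        d = (species == sp).astype(float)
        cols[f"species[{sp}]"] = d
        cols[f"log10_mass:species[{sp}]"] = d * log10_mass
    return pd.DataFrame(cols)


class ThermalOntogenyModel:
    """OLS model ``temperature ~ log10(mass) * species`` for one location.

    Parameters
    ----------
    data
        Derived sample table restricted to one location, with finite
        temperature and positive body mass. Records failing either are
        dropped with a count.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        temperature_col: str = "temperature_C",
        mass_col: str = "body_mass_g",
        species_col: str = "species",
    ):
        d = data.copy()
        for col in (temperature_col, mass_col, species_col):
            if col not in d.columns:
                raise DataError(f"column {col!r} missing from input")
        usable = (
            pd.to_numeric(d[temperature_col], errors="coerce").notna()
            & pd.to_numeric(d[mass_col], errors="coerce").notna()
            & (d[mass_col] > 0)
        )
        self.n_dropped = int((~usable).sum())
        d = d.loc[usable]
        self.species_levels = sorted(d[species_col].unique())
        if len(self.species_levels) < 2:
            raise FitError("thermal ontogeny model needs at least two species")
        for sp in self.species_levels:
            grp = d.loc[d[species_col] == sp, mass_col]
            if len(grp) < 3 or grp.nunique() < 2:
                raise FitError(
                    f"species {sp!r} needs >=3 individuals spanning more than "
                    "one body-mass value"
                )
        self.reference_species = self.species_levels[0]
        self.data = d.reset_index(drop=True)
        self._cols = (temperature_col, mass_col, species_col)

    def fit(self) -> "ThermalOntogenyResults":
        tcol, mcol, scol = self._cols
        y = self.data[tcol].to_numpy(dtype=float)
        x = np.log10(self.data[mcol].to_numpy(dtype=float))
        X = _design(x, self.data[scol], self.species_levels)
        res = sm.OLS(y, X).fit()
        return ThermalOntogenyResults(self, res)


@dataclass
class _MassRange:
    lo: float
    hi: float


class ThermalOntogenyResults:
    """Fitted thermal-niche model: coefficients, contrasts, predictions."""

    def __init__(self, model: ThermalOntogenyModel, sm_results):
        self.model = model
        self._res = sm_results
        self.params = sm_results.params
        self.bse = sm_results.bse
        self.nobs = int(sm_results.nobs)
        self.df_resid = float(sm_results.df_resid)
        self.resid_sd = float(np.sqrt(sm_results.mse_resid))
        self.species_levels = model.species_levels
        self.reference_species = model.reference_species
        _, mcol, scol = model._cols
        self._mass_ranges = {
            sp: _MassRange(
                float(model.data.loc[model.data[scol] == sp, mcol].min()),
                float(model.data.loc[model.data[scol] == sp, mcol].max()),
            )
            for sp in self.species_levels
        }

    # -- prediction ------------------------------------------------------

    def _row(self, mass_g: float, species: str) -> np.ndarray:
        x = np.log10(mass_g)
        row = {name: 0.0 for name in self.params.index}
        row["Intercept"] = 1.0
        row["log10_mass"] = x
        if species != self.reference_species:
            row[f"species[{species}]"] = 1.0
            row[f"log10_mass:species[{species}]"] = x
        return np.array([row[name] for name in self.params.index])

    def predict(self, mass_g, species: str) -> np.ndarray:
        """Point prediction of experienced temperature (deg C)."""
        masses = np.atleast_1d(np.asarray(mass_g, dtype=float))
        rows = np.vstack([self._row(m, species) for m in masses])
        out = rows @ self.params.to_numpy()
        return float(out[0]) if np.isscalar(mass_g) else out

    def prediction_grid(self, n: int = 50, level: float = 0.95) -> pd.DataFrame:
        """Per-species mass grid with predictions and confidence band."""
        frames = []
        for sp in self.species_levels:
            r = self._mass_ranges[sp]
            grid = np.geomspace(r.lo, r.hi, n)
            rows = np.vstack([self._row(m, sp) for m in grid])
            pred = self._res.get_prediction(
                pd.DataFrame(rows, columns=self.params.index)
            )
            frame = pred.summary_frame(alpha=1 - level)
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "body_mass_g": grid,
                        "temperature_C": frame["mean"].to_numpy(),
                        "ci_low": frame["mean_ci_lower"].to_numpy(),
                        "ci_high": frame["mean_ci_upper"].to_numpy(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    # -- inference -------------------------------------------------------

    def slope(self, species: str) -> float:
        """Fitted ontogenetic slope (deg C per log10 g) for a species."""
        b = float(self.params["log10_mass"])
        if species != self.reference_species:
            b += float(self.params[f"log10_mass:species[{species}]"])
        return b

    def interaction_ftest(self):
        """F test of the mass-by-species interaction block.

        Refits the additive design and compares residual sums of squares.
        Returns ``(F, p, df_num, df_den)``.
        """
        tcol, mcol, scol = self.model._cols
        d = self.model.data
        y = d[tcol].to_numpy(dtype=float)
        x = np.log10(d[mcol].to_numpy(dtype=float))
        full = _design(x, d[scol], self.species_levels)
        additive = full[[c for c in full.columns if not c.startswith("log10_mass:")]]
        res_add = sm.OLS(y, additive).fit()
        q = full.shape[1] - additive.shape[1]
        f = ((res_add.ssr - self._res.ssr) / q) / self._res.mse_resid
        p = float(stats.f.sf(f, q, self.df_resid))
        return float(f), p, q, self.df_resid

    def tukey_contrasts(self, at_mass: Optional[float] = None) -> pd.DataFrame:
        """All pairwise species temperature differences at a common mass.

        The difference for pair (a, b) is evaluated at ``at_mass`` grams,
        defaulting per pair to the geometric mean of the overlapping
        observed mass range (of the combined range when the pair does not
        overlap; the row is then flagged ``extrapolated``). Family-wise
        adjustment uses the studentized-range (Tukey-Kramer) distribution
        with as many groups as species.
        """
        k = len(self.species_levels)
        V = self._res.cov_params().to_numpy()
        beta = self.params.to_numpy()
        rows = []
        for sp_a, sp_b in itertools.combinations(self.species_levels, 2):
            ra, rb = self._mass_ranges[sp_a], self._mass_ranges[sp_b]
            extrapolated = False
            if at_mass is None:
                lo, hi = max(ra.lo, rb.lo), min(ra.hi, rb.hi)
                if lo <= hi:
                    m = float(np.sqrt(lo * hi))
                else:
                    m = float(np.sqrt(min(ra.lo, rb.lo) * max(ra.hi, rb.hi)))
                    extrapolated = True
            else:
                m = float(at_mass)
                extrapolated = not (
                    ra.lo <= m <= ra.hi and rb.lo <= m <= rb.hi
                )
            c = self._row(m, sp_a) - self._row(m, sp_b)
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            t = abs(est) / se
            p_unadj = 2 * float(stats.t.sf(t, self.df_resid))
            p_adj = float(
                stats.studentized_range.sf(np.sqrt(2.0) * t, k, self.df_resid)
            )
            p_adj = min(1.0, max(p_adj, p_unadj))
            rows.append(
                {
                    "species_a": sp_a,
                    "species_b": sp_b,
                    "at_mass_g": m,
                    "estimate_C": est,
                    "se": se,
                    "p_unadjusted": p_unadj,
                    "p_adjusted": p_adj,
                    "significant": p_adj < 0.05,
                    "extrapolated": extrapolated,
                }
            )
        return pd.DataFrame(rows)

    def coefficient_table(self) -> pd.DataFrame:
        ci = self._res.conf_int()
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Ontogenetic thermal-niche model (OLS)",
            f"  n = {self.nobs}, residual sd = {self.resid_sd:.3f} degC, "
            f"reference species = {self.reference_species}",
            "  term                                estimate      se",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<34s} {self.params[name]:>9.4f} {self.bse[name]:>8.4f}"
            )
        lines.append("  per-species ontogenetic slopes (degC per log10 g):")
        for sp in self.species_levels:
            lines.append(f"    {sp:<16s} {self.slope(sp):>7.3f}")
        return "\n".join(lines)


def crs_band_summary(
    data: pd.DataFrame,
    config: EnvCalibConfig,
    species: str,
    crs_min_cm: Optional[float] = None,
    crs_max_cm: Optional[float] = None,
    temperature_col: str = "temperature_C",
    mass_col: str = "body_mass_g",
    species_col: str = "species",
) -> dict:
    """Experienced-temperature overlap across the retainable size band.

    Converts the minimum / maximum conservation reference sizes (total
    length, cm) to body masses with the species length-weight coefficients
    and compares the experienced-temperature ranges of fish below the
    minimum-CRS mass and above the maximum-CRS mass. An overlap width of
    zero means harvestable-size fish thermally separate the two groups.
    """
    if crs_min_cm is None or crs_max_cm is None:
        if species not in config.crs_limits_cm:
            raise DataError(f"no CRS limits configured for species {species!r}")
        crs_min_cm, crs_max_cm = config.crs_limits_cm[species]
    m_min = mass_from_length(crs_min_cm, species, config)
    m_max = mass_from_length(crs_max_cm, species, config)
    d = data.loc[
        (data[species_col] == species)
        & pd.to_numeric(data[temperature_col], errors="coerce").notna()
    ]
    below = d.loc[d[mass_col] < m_min, temperature_col].astype(float)
    above = d.loc[d[mass_col] > m_max, temperature_col].astype(float)
    out = {
        "species": species,
        "crs_min_cm": float(crs_min_cm),
        "crs_max_cm": float(crs_max_cm),
        "mass_at_crs_min_g": float(m_min),
        "mass_at_crs_max_g": float(m_max),
        "n_below": int(len(below)),
        "n_above": int(len(above)),
    }
    if below.empty or above.empty:
        out.update(
            below_range_C=None, above_range_C=None, overlap_C=None,
            note="one or both groups empty; overlap undefined",
        )
        return out
    b_lo, b_hi = float(below.min()), float(below.max())
    a_lo, a_hi = float(above.min()), float(above.max())
    overlap = max(0.0, min(b_hi, a_hi) - max(b_lo, a_lo))
    out.update(
        below_range_C=(b_lo, b_hi),
        above_range_C=(a_lo, a_hi),
        overlap_C=float(overlap),
    )
    return out
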