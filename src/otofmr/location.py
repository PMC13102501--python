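"""Standardized model of FMR in large individuals across locations.

Once wrasse have completed their ontogenetic descent into cooler adult
habitat, mass and temperature are less confounded, so the sample is first
restricted to large individuals (per-species body-mass floors). On that
subset a Gaussian linear model of ln FMR is fitted with z-scored
continuous predictors:

    ln FMR ~ z(ln mass) + z(inverse temperature) + Species + Location

where inverse temperature is 1/(k T_Kelvin) in eV^-1, so that the
rescaled temperature slope is directly an activation energy in eV and the
rescaled mass slope a dimensionless allometric exponent. Species and
location enter as factors (reference levels: alphabetically first), either
additively or with a species-by-location interaction; candidate structures
are ranked by an information criterion (AICc for the likelihood backend,
DIC for the MCMC backend). Intercept-like coefficients back-transform to
mgO2 kg^-1 hr^-1 by exponentiation.

The likelihood backend (statsmodels OLS, default) is exact and fast; the
Bayesian backend (emcee ensemble MCMC, weakly informative priors:
Normal(0, 5^2) on coefficients, half-Normal(0, 2.5) on the residual sd)
gives posterior summaries and DIC and is seed-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import EnvCalibConfig
from .exceptions import DataError, FitError
from .proxies import inverse_temperature

__all__ = [
    "select_large_individuals",
    "standardize",
    "StandardizationMeta",
    "FMRLocationModel",
    "FMRLocationResults",
    "compare_models",
    "DEFAULT_SEED",
]

#: Default seed for the stochastic (MCMC) path; sampling month of the study.
DEFAULT_SEED = 20191001


def select_large_individuals(
    data: pd.DataFrame,
    thresholds: Optional[Dict[str, float]] = None,
    config: Optional[EnvCalibConfig] = None,
    mass_col: str = "body_mass_g",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Subset to body mass >= per-species threshold.

    Thresholds default to the configured per-species large-individual
    floors; every species present must have one. Returns the subset and
    per-species retained counts.
    """
    if thresholds is None:
        cfg = config or EnvCalibConfig()
        thresholds = cfg.large_thresholds
    species = data["species"].unique()
    missing = [sp for sp in species if sp not in thresholds]
    if missing:
        raise DataError(
            f"no large-individual threshold for species: {sorted(missing)}"
        )
    thr = data["species"].map(thresholds)
    keep = pd.to_numeric(data[mass_col], errors="coerce") >= thr
    subset = data.loc[keep]
    counts = {sp: int((subset["species"] == sp).sum()) for sp in sorted(species)}
    return subset, counts


@dataclass
class StandardizationMeta:
    """Means and sds used to z-score the continuous predictors."""

    mean_ln_mass: float
    sd_ln_mass: float
    mean_inv_temp: float
    sd_inv_temp: float
    thresholds: Dict[str, float] = field(default_factory=dict)
    n_dropped_nonpositive_fmr: int = 0


def standardize(
    subset: pd.DataFrame,
    config: Optional[EnvCalibConfig] = None,
    mass_col: str = "body_mass_g",
    temperature_col: str = "temperature_C",
    fmr_col: str = "fmr_mgO2_kg_hr",
) -> Tuple[pd.DataFrame, StandardizationMeta]:
    """Add ln_fmr, z_ln_mass and z_inv_temp columns (sample sd, ddof=1).

    Records with non-positive or missing FMR are dropped (counted in the
    meta) since the response is ln FMR. Zero variance in a predictor is an
    error naming the predictor.
    """
    cfg = config or EnvCalibConfig()
    d = subset.copy()
    ok = (
        pd.to_numeric(d[fmr_col], errors="coerce").notna()
        & (d[fmr_col] > 0)
        & pd.to_numeric(d[mass_col], errors="coerce").notna()
        & pd.to_numeric(d[temperature_col], errors="coerce").notna()
    )
    n_dropped = int((~ok).sum())
    d = d.loc[ok].copy()
    ln_mass = np.log(d[mass_col].to_numpy(dtype=float))
    inv_t = inverse_temperature(d[temperature_col].to_numpy(dtype=float), cfg)
    meta = StandardizationMeta(
        mean_ln_mass=float(np.mean(ln_mass)),
        sd_ln_mass=float(np.std(ln_mass, ddof=1)) if len(ln_mass) > 1 else 0.0,
        mean_inv_temp=float(np.mean(inv_t)),
        sd_inv_temp=float(np.std(inv_t, ddof=1)) if len(inv_t) > 1 else 0.0,
        n_dropped_nonpositive_fmr=n_dropped,
    )
    for name, sd in (("ln mass", meta.sd_ln_mass), ("inverse temperature", meta.sd_inv_temp)):
        if sd == 0:
            raise DataError(f"predictor {name!r} has zero variance on the subset")
    d["ln_fmr"] = np.log(d[fmr_col].to_numpy(dtype=float))
    d["z_ln_mass"] = (ln_mass - meta.mean_ln_mass) / meta.sd_ln_mass
    d["z_inv_temp"] = (inv_t - meta.mean_inv_temp) / meta.sd_inv_temp
    return d, meta


def _build_design(
    d: pd.DataFrame,
    species_levels: Sequence[str],
    location_levels: Sequence[str],
    variant: str,
) -> pd.DataFrame:
    cols = {
        "Intercept": np.ones(len(d)),
        "z_ln_mass": d["z_ln_mass"].to_numpy(dtype=float),
        "z_inv_temp": d["z_inv_temp"].to_numpy(dtype=float),
    }
    sp = d["species"].to_numpy()
    loc = d["location"].to_numpy()
    for s in species_levels[1:]:
        cols[f"species[{s}]"] = (sp == s).astype(float)
    for l in location_levels[1:]:
        cols[f"location[{l}]"] = (loc == l).astype(float)
    if variant == "interaction":
        for s in species_levels[1:]:
            for l in location_levels[1:]:
                cols[f"species[{s}]:location[{l}]"] = (
                    (sp == s) & (loc == l)
                ).astype(float)
    elif variant != "additive":
        raise DataError(f"unknown model variant {variant!r}")
    return pd.DataFrame(cols, index=d.index)


class FMRLocationModel:
    """Standardized GLM of ln FMR in large individuals.

    Parameters
    ----------
    data
        Derived sample table (all sizes); the large-individual subset and
        the z-scoring are computed here and recorded in the results.
    variant
        ``"additive"`` (species + location) or ``"interaction"``
        (adds species-by-location terms).
    backend
        ``"mle"`` (statsmodels OLS with t intervals and AICc) or
        ``"bayes"`` (emcee MCMC with credible intervals and DIC).
    thresholds
        Per-species large-individual floors (g); defaults to the
        configured values.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        variant: str = "additive",
        backend: str = "mle",
        config: Optional[EnvCalibConfig] = None,
        thresholds: Optional[Dict[str, float]] = None,
    ):
        if backend not in ("mle", "bayes"):
            raise DataError(f"unknown backend {backend!r}")
        self.variant = variant
        self.backend = backend
        self.config = config or EnvCalibConfig()
        subset, counts = select_large_individuals(
            data, thresholds=thresholds, config=self.config
        )
        if len(subset) == 0:
            raise FitError("no records at or above the large-individual thresholds")
        d, meta = standardize(subset, self.config)
        meta.thresholds = dict(
            thresholds if thresholds is not None else self.config.large_thresholds
        )
        self.meta = meta
        self.subset_counts = counts
        self.species_levels = sorted(d["species"].unique())
        self.location_levels = sorted(d["location"].unique())
        if len(self.species_levels) < 2:
            raise FitError("location model needs at least two species")
        self.data = d.reset_index(drop=True)
        self.X = _build_design(
            self.data, self.species_levels, self.location_levels, variant
        ).reset_index(drop=True)
        self.y = self.data["ln_fmr"].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(self.X.to_numpy())
        if rank < self.X.shape[1]:
            counts_cell = (
                self.data.groupby(["species", "location"]).size().to_dict()
            )
            raise FitError(
                "rank-deficient design "
                f"(rank {rank} < {self.X.shape[1]} columns); "
                f"per-cell counts: {counts_cell}"
            )
        self.reference_species = self.species_levels[0]
        self.reference_location = self.location_levels[0]
        # per-species median mass of the modelling subset (for predictions)
        self.median_mass_g = {
            sp: float(self.data.loc[self.data["species"] == sp, "body_mass_g"].median())
            for sp in self.species_levels
        }

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        seed: Optional[int] = None,
        draws: int = 1500,
        burn: int = 500,
        prior_sd: float = 5.0,
        prior_sigma_scale: float = 2.5,
    ) -> "FMRLocationResults":
        if self.backend == "mle":
            return self._fit_mle()
        return self._fit_bayes(
            seed=DEFAULT_SEED if seed is None else seed,
            draws=draws, burn=burn,
            prior_sd=prior_sd, prior_sigma_scale=prior_sigma_scale,
        )

    def _fit_mle(self) -> "FMRLocationResults":
        res = sm.OLS(self.y, self.X).fit()
        ci = res.conf_int(alpha=0.05)
        table = pd.DataFrame(
            {
                "term": self.X.columns,
                "mean": res.params.to_numpy(),
                "se": res.bse.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
            }
        )
        n = len(self.y)
        k = self.X.shape[1] + 1  # mean parameters + residual sd
        aic = -2 * res.llf + 2 * k
        if n - k - 1 > 0:
            aicc = aic + 2 * k * (k + 1) / (n - k - 1)
        else:
            aicc = np.inf
        return FMRLocationResults(
            model=self,
            coef_table=table,
            criterion_name="AICc",
            criterion=float(aicc),
            cov=res.cov_params().to_numpy(),
            resid_sd=float(np.sqrt(res.mse_resid)),
            draws=None,
            seed=None,
        )

    def _log_posterior(self, theta, prior_sd, prior_sigma_scale):
        p = self.X.shape[1]
        beta, log_s = theta[:p], theta[p]
        if abs(log_s) > 20:
            return -np.inf
        s = np.exp(log_s)
        resid = self.y - self.X.to_numpy() @ beta
        n = len(self.y)
        ll = -0.5 * n * np.log(2 * np.pi * s**2) - 0.5 * np.dot(resid, resid) / s**2
        lp = -0.5 * np.dot(beta, beta) / prior_sd**2
        lp += -0.5 * (s / prior_sigma_scale) ** 2 + log_s  # half-normal + Jacobian
        return ll + lp

    def _fit_bayes(self, seed, draws, burn, prior_sd, prior_sigma_scale):
        import emcee

        p = self.X.shape[1]
        ndim = p + 1
        nwalkers = max(2 * ndim + 2, 24)
        mle = self._fit_mle()
        center = np.concatenate(
            [mle.coef_table["mean"].to_numpy(), [np.log(mle.resid_sd)]]
        )
        rng = np.random.default_rng(seed)
        p0 = center + 1e-3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, self._log_posterior,
            args=(prior_sd, prior_sigma_scale),
        )
        sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
        sampler.run_mcmc(p0, burn + draws, progress=False)
        chain = sampler.get_chain(discard=burn, thin=4, flat=True)
        betas = chain[:, :p]
        sigmas = np.exp(chain[:, p])
        mean = betas.mean(axis=0)
        lo = np.percentile(betas, 2.5, axis=0)
        hi = np.percentile(betas, 97.5, axis=0)
        se = betas.std(axis=0, ddof=1)
        table = pd.DataFrame(
            {"term": self.X.columns, "mean": mean, "se": se,
             "ci_low": lo, "ci_high": hi}
        )
        # DIC from the Gaussian deviance
        Xn = self.X.to_numpy()

        def deviance(beta, s):
            resid = self.y - Xn @ beta
            n = len(self.y)
            return n * np.log(2 * np.pi * s**2) + np.dot(resid, resid) / s**2

        devs = np.array([deviance(b, s) for b, s in zip(betas, sigmas)])
        d_hat = deviance(mean, float(sigmas.mean()))
        dic = float(2 * devs.mean() - d_hat)
        return FMRLocationResults(
            model=self,
            coef_table=table,
            criterion_name="DIC",
            criterion=dic,
            cov=np.cov(betas, rowvar=False),
            resid_sd=float(sigmas.mean()),
            draws=chain,
            seed=seed,
        )


class FMRLocationResults:
    """Fitted standardized FMR model with back-transformation utilities."""

    def __init__(self, model, coef_table, criterion_name, criterion, cov,
                 resid_sd, draws, seed):
        self.model = model
        self.variant = model.variant
        self.backend = model.backend
        self.meta = model.meta
        self.coef_table = coef_table
        self.criterion_name = criterion_name
        self.criterion = float(criterion)
        self.cov = cov
        self.resid_sd = resid_sd
        self.draws = draws
        self.seed = seed
        self.nobs = len(model.y)
        self.n_params = model.X.shape[1]
        self._params = dict(zip(coef_table["term"], coef_table["mean"]))
        self._response_checksum = float(np.sum(model.y))

    def __getitem__(self, term: str) -> float:
        return self._params[term]

    # -- back-transformation ---------------------------------------------

    def rescale(self) -> pd.DataFrame:
        """Natural-unit coefficients.

        Intercept and species rows exponentiate (adding the intercept for
        species offsets) to mgO2 kg^-1 hr^-1; the standardized mass slope
        divides by sd(ln mass) to a dimensionless allometric exponent; the
        standardized inverse-temperature slope divides by sd(1/(kT)) to an
        activation energy in eV; location rows exponentiate to an FMR
        ratio between locations.
        """
        meta = self.meta
        rows = []
        intercept = self._params["Intercept"]
        for term, mean in self._params.items():
            if term == "Intercept":
                rows.append((term, mean, np.exp(mean), "mgO2 kg-1 hr-1"))
            elif term == "z_ln_mass":
                rows.append((term, mean, mean / meta.sd_ln_mass, "dimensionless (alpha)"))
            elif term == "z_inv_temp":
                rows.append((term, mean, mean / meta.sd_inv_temp, "eV (E)"))
            elif term.startswith("species[") and ":" not in term:
                rows.append((term, mean, np.exp(intercept + mean), "mgO2 kg-1 hr-1"))
            elif term.startswith("location["):
                rows.append((term, mean, np.exp(mean), "FMR ratio vs reference location"))
            else:  # interaction terms: leave on the ln scale
                rows.append((term, mean, np.nan, "ln-scale interaction"))
        out = pd.DataFrame(rows, columns=["term", "mean", "rescaled", "unit"])
        return out.merge(
            self.coef_table[["term", "ci_low", "ci_high"]], on="term", how="left"
        )

    # -- prediction ------------------------------------------------------

    def _x_row(self, species, location, mass_g, temperature_c) -> np.ndarray:
        meta, cfg = self.meta, self.model.config
        row = {t: 0.0 for t in self._params}
        row["Intercept"] = 1.0
        row["z_ln_mass"] = (np.log(mass_g) - meta.mean_ln_mass) / meta.sd_ln_mass
        row["z_inv_temp"] = (
            inverse_temperature(temperature_c, cfg) - meta.mean_inv_temp
        ) / meta.sd_inv_temp
        if species != self.model.reference_species:
            row[f"species[{species}]"] = 1.0
        if location != self.model.reference_location:
            row[f"location[{location}]"] = 1.0
        key = f"species[{species}]:location[{location}]"
        if key in row:
            row[key] = 1.0
        return np.array([row[t] for t in self._params])

    def predict_common(
        self,
        common_temperature_c: float = 10.5,
        common_mass_g: float = 81.0,
        median_masses: Optional[Dict[str, float]] = None,
        level: float = 0.95,
    ) -> pd.DataFrame:
        """FMR predictions at a common temperature for every species/location.

        Two mass bases per species: its median mass in the modelling
        subset, and a single common mass shared by all species. Point
        predictions and normal-approximation intervals are exponentiated
        to the FMR scale. Conditions outside the observed subset range are
        flagged ``extrapolated``.
        """
        medians = median_masses or self.model.median_mass_g
        z = float(stats.norm.ppf(0.5 + level / 2))
        obs_mass = self.model.data["body_mass_g"]
        obs_temp = self.model.data["temperature_C"]
        rows = []
        beta = np.array([self._params[t] for t in self._params])
        for sp in self.model.species_levels:
            for loc in self.model.location_levels:
                for basis, m in (("species_median", medians[sp]),
                                 ("common", common_mass_g)):
                    x = self._x_row(sp, loc, m, common_temperature_c)
                    lp = float(x @ beta)
                    se = float(np.sqrt(x @ self.cov @ x))
                    rows.append(
                        {
                            "species": sp,
                            "location": loc,
                            "mass_basis": basis,
                            "mass_g": float(m),
                            "temperature_C": float(common_temperature_c),
                            "fmr_mgO2_kg_hr": float(np.exp(lp)),
                            "ci_low": float(np.exp(lp - z * se)),
                            "ci_high": float(np.exp(lp + z * se)),
                            "extrapolated": bool(
                                m < obs_mass.min() or m > obs_mass.max()
                                or common_temperature_c < obs_temp.min()
                                or common_temperature_c > obs_temp.max()
                            ),
                        }
                    )
        out = pd.DataFrame(rows)
        if out["extrapolated"].any():
            warnings.warn(
                "some common-condition predictions extrapolate beyond the "
                "observed subset range", stacklevel=2,
            )
        return out

    def summary(self) -> str:
        lines = [
            f"Standardized FMR model ({self.variant}, backend={self.backend})",
            f"  n = {self.nobs} large individuals; "
            f"{self.criterion_name} = {self.criterion:.2f}; "
            f"residual sd (ln FMR) = {self.resid_sd:.3f}",
            f"  reference: species {self.model.reference_species!r}, "
            f"location {self.model.reference_location!r}",
            "  term                          mean     2.5%    97.5%  rescaled",
        ]
        resc = self.rescale().set_index("term")
        for _, r in self.coef_table.iterrows():
            rv = resc.loc[r["term"], "rescaled"]
            rs = f"{rv:9.2f}" if np.isfinite(rv) else "        -"
            lines.append(
                f"  {r['term']:<28s} {r['mean']:>7.3f} {r['ci_low']:>8.3f} "
                f"{r['ci_high']:>8.3f} {rs}"
            )
        return "\n".join(lines)


def compare_models(results: List[FMRLocationResults]) -> Tuple[pd.DataFrame, FMRLocationResults]:
    """Rank candidate model structures by their information criterion.

    All results must come from the same subset and response (checked via
    n and the response checksum) and use the same criterion. Lower wins;
    ties break toward fewer parameters.
    """
    if len(results) < 2:
        raise DataError("model comparison needs at least two fitted results")
    first = results[0]
    for r in results[1:]:
        if r.nobs != first.nobs or not np.isclose(
            r._response_checksum, first._response_checksum
        ):
            raise DataError("results were fitted on different subsets or responses")
        if r.criterion_name != first.criterion_name:
            raise DataError("results use different information criteria")
    order = sorted(results, key=lambda r: (r.criterion, r.n_params))
    table = pd.DataFrame(
        {
            "variant": [r.variant for r in order],
            "criterion_name": [r.criterion_name for r in order],
            "criterion": [r.criterion for r in order],
            "delta": [r.criterion - order[0].criterion for r in order],
            "n_params": [r.n_params for r in order],
        }
    )
    return table, order[0]
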