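"""Standardized location model: subsetting, z-scoring, fit, rescaling."""

import copy

import numpy as np
import pandas as pd
import pytest

import otofmr as o
from otofmr.exceptions import DataError


@pytest.fixture(scope="module")
def common_cohort():
    """Common-slope cohort where the additive GLM is correctly specified."""
    species, locations = o.default_params()
    species = o.scenario_common_scaling(species)
    cfg = o.simulation_config(locations, species)
    samples, truth = o.simulate_cohort(species, locations, seed=909, n_per_cell=120)
    derived, _ = o.derive_all(samples, cfg)
    return derived, cfg


class TestSelection:
    def test_counting_example(self):
        d = pd.DataFrame({"species": "X", "body_mass_g": [10.0, 25.0, 40.0]})
        subset, counts = o.select_large_individuals(d, thresholds={"X": 30.0})
        assert len(subset) == 1 and counts == {"X": 1}

    def test_zero_threshold_is_identity(self):
        d = pd.DataFrame({"species": "X", "body_mass_g": [10.0, 25.0, 40.0]})
        subset, _ = o.select_large_individuals(d, thresholds={"X": 0.0})
        pd.testing.assert_frame_equal(subset, d)

    def test_matches_brute_force_filter(self, common_cohort):
        derived, cfg = common_cohort
        subset, counts = o.select_large_individuals(derived, config=cfg)
        brute = derived[
            derived.apply(
                lambda r: r.body_mass_g >= cfg.large_thresholds[r.species], axis=1
            )
        ]
        assert len(subset) == len(brute)
        assert sum(counts.values()) == len(brute)

    def test_missing_threshold_is_error(self):
        d = pd.DataFrame({"species": ["X", "Q"], "body_mass_g": [10.0, 20.0]})
        with pytest.raises(DataError, match="Q"):
            o.select_large_individuals(d, thresholds={"X": 5.0})


class TestStandardize:
    def test_z_columns_mean_zero_sd_one(self, common_cohort):
        derived, cfg = common_cohort
        subset, _ = o.select_large_individuals(derived, config=cfg)
        z, meta = o.standardize(subset, cfg)
        for col in ("z_ln_mass", "z_inv_temp"):
            assert abs(z[col].mean()) < 1e-10
            assert z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_round_trip_to_raw_scale(self, common_cohort):
        derived, cfg = common_cohort
        subset, _ = o.select_large_individuals(derived, config=cfg)
        z, meta = o.standardize(subset, cfg)
        back = np.exp(z["z_ln_mass"] * meta.sd_ln_mass + meta.mean_ln_mass)
        assert np.max(np.abs(back - z["body_mass_g"])) < 1e-8

    def test_constant_predictor_is_error(self):
        d = pd.DataFrame(
            {
                "species": "X",
                "location": "Dorset",
                "body_mass_g": [10.0, 20.0, 30.0],
                "temperature_C": 12.0,
                "fmr_mgO2_kg_hr": [50.0, 60.0, 70.0],
            }
        )
        with pytest.raises(DataError, match="inverse temperature"):
            o.standardize(d)


class TestFit:
    def test_noise_free_limit_recovers_generative_truth(self):
        species, locations = o.default_params()
        alpha, e_ev = -0.53, -1.66
        species = [
            o.SpeciesSimParams(
                s.species, s.mass_min_g, s.mass_max_g, s.t_at_1g_c,
                s.thermal_slope, s.temp_noise_sd_c, s.b0_ref,
                alpha, e_ev, fmr_noise_sd_ln=0.0, diet_missing_frac=0.0,
            )
            for s in species
        ]
        cfg = o.simulation_config(locations, species)
        samples, _ = o.simulate_cohort(species, locations, seed=77, n_per_cell=80)
        derived, _ = o.derive_all(samples, cfg)
        res = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        resc = res.rescale().set_index("term")
        assert resc.loc["z_ln_mass", "rescaled"] == pytest.approx(alpha, abs=1e-4)
        assert resc.loc["z_inv_temp", "rescaled"] == pytest.approx(e_ev, abs=1e-4)
        assert res["location[Skye]"] == pytest.approx(0.0, abs=1e-6)

    def test_nested_consistency_between_variants(self, common_cohort):
        derived, cfg = common_cohort
        add = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        inter = o.FMRLocationModel(derived, variant="interaction", config=cfg).fit()
        a = add.coef_table.set_index("term")
        b = inter.coef_table.set_index("term")
        for term in ("z_ln_mass", "z_inv_temp"):
            assert abs(a.loc[term, "mean"] - b.loc[term, "mean"]) < 2 * (
                a.loc[term, "se"] + b.loc[term, "se"]
            )

    def test_bayes_backend_matches_mle_and_is_seeded(self, common_cohort):
        derived, cfg = common_cohort
        model = o.FMRLocationModel(derived, variant="additive",
                                   backend="bayes", config=cfg)
        r1 = model.fit(seed=123)
        r2 = o.FMRLocationModel(derived, variant="additive",
                                backend="bayes", config=cfg).fit(seed=123)
        assert np.allclose(r1.coef_table["mean"], r2.coef_table["mean"])
        assert r1.criterion_name == "DIC" and np.isfinite(r1.criterion)
        mle = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        diff = np.abs(
            r1.coef_table["mean"].to_numpy() - mle.coef_table["mean"].to_numpy()
        )
        assert np.max(diff) < 0.15
        assert (r1.coef_table.ci_low <= r1.coef_table["mean"]).all()
        assert (r1.coef_table["mean"] <= r1.coef_table.ci_high).all()


class TestRescaleAndPredict:
    def test_rescaled_levels_are_exponentials(self, common_cohort):
        derived, cfg = common_cohort
        res = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        resc = res.rescale().set_index("term")
        b0 = res["Intercept"]
        assert resc.loc["Intercept", "rescaled"] == pytest.approx(np.exp(b0))
        for sp in res.model.species_levels[1:]:
            term = f"species[{sp}]"
            assert resc.loc[term, "rescaled"] == pytest.approx(
                np.exp(b0 + res[term])
            )

    def test_location_prediction_ratio_is_exp_coefficient(self, common_cohort):
        derived, cfg = common_cohort
        res = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        pred = res.predict_common(common_temperature_c=10.5, common_mass_g=81.0)
        ratio = np.exp(res["location[Skye]"])
        piv = pred[pred.mass_basis == "common"].pivot_table(
            index="species", columns="location", values="fmr_mgO2_kg_hr"
        )
        assert np.allclose(piv["Skye"] / piv["Dorset"], ratio)
        assert (pred["fmr_mgO2_kg_hr"] > 0).all()

    def test_reference_prediction_is_exp_intercept(self, common_cohort):
        derived, cfg = common_cohort
        res = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        meta = res.meta
        m_anchor = float(np.exp(meta.mean_ln_mass))
        t_anchor = 1.0 / (cfg.boltzmann_k * meta.mean_inv_temp) - cfg.kelvin_offset
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = res.predict_common(
                common_temperature_c=t_anchor,
                common_mass_g=m_anchor,
            )
        row = pred[
            (pred.species == res.model.reference_species)
            & (pred.location == res.model.reference_location)
            & (pred.mass_basis == "common")
        ].iloc[0]
        assert row.fmr_mgO2_kg_hr == pytest.approx(np.exp(res["Intercept"]), rel=1e-9)


class TestCompare:
    def test_different_subsets_rejected(self, common_cohort):
        derived, cfg = common_cohort
        r1 = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        r2 = o.FMRLocationModel(
            derived.iloc[: len(derived) // 2], variant="additive", config=cfg
        ).fit()
        with pytest.raises(DataError, match="different subsets"):
            o.compare_models([r1, r2])

    def test_mixed_criteria_rejected(self, common_cohort):
        derived, cfg = common_cohort
        r1 = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        r2 = o.FMRLocationModel(
            derived, variant="additive", backend="bayes", config=cfg
        ).fit(seed=5)
        with pytest.raises(DataError, match="criteria"):
            o.compare_models([r1, r2])

    def test_tie_broken_toward_fewer_parameters(self, common_cohort):
        derived, cfg = common_cohort
        r1 = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
        r2 = copy.copy(r1)
        r2.variant = "padded"
        r2.n_params = r1.n_params + 4  # same criterion, more parameters
        table, best = o.compare_models([r2, r1])
        assert best.variant == "additive"
        assert table.iloc[0].variant == "additive"
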