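"""Proxy conversions: worked examples, exact inverses, flag propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import otofmr as o
from otofmr.exceptions import ComputationError, ConfigurationError, DataError

CFG = o.EnvCalibConfig(lw_coeffs={"X": (0.01, 3.0), "Y": (1.0, 1.0)})

finite = dict(allow_nan=False, allow_infinity=False)


class TestMassLength:
    @pytest.mark.parametrize(
        "length,species,expected",
        [(10.0, "X", 10.0), (1.0, "Y", 1.0)],
    )
    def test_worked_examples(self, length, species, expected):
        assert o.mass_from_length(length, species, CFG) == pytest.approx(expected)

    def test_cubic_doubling_gives_factor_eight(self):
        m10 = o.mass_from_length(10.0, "X", CFG)
        m20 = o.mass_from_length(20.0, "X", CFG)
        assert m20 / m10 == pytest.approx(8.0)

    def test_monotone_in_length(self):
        lengths = np.linspace(1, 50, 60)
        masses = o.mass_from_length(lengths, "X", CFG)
        assert np.all(np.diff(masses) > 0)

    def test_unknown_species_names_species(self):
        with pytest.raises(ConfigurationError, match="Z"):
            o.mass_from_length(10.0, "Z", CFG)


class TestThermometry:
    def test_intercept_case_is_zero_celsius(self):
        # offset equal to the fractionation intercept -> 0 degC
        d18o = 0.5 + 3.465
        assert o.temperature_from_d18o(d18o, "Dorset", CFG) == pytest.approx(0.0)

    def test_dorset_validation_value(self):
        # (3.465 - (1.018 - 0.5)) / 0.209 = 14.10
        t = o.temperature_from_d18o(1.018, "Dorset", CFG)
        assert t == pytest.approx(14.10, abs=0.01)

    def test_forward_examples(self):
        cfg0 = o.EnvCalibConfig(d18o_sw={"A": 0.0, "Skye": 0.3})
        assert o.d18o_from_temperature(0.0, "A", cfg0) == pytest.approx(3.465)
        assert o.d18o_from_temperature(10.0, "Skye", cfg0) == pytest.approx(1.675)

    def test_round_trip_on_temperature_grid(self):
        t = np.linspace(-2, 30, 100)
        back = o.temperature_from_d18o(
            o.d18o_from_temperature(t, "Skye", CFG), "Skye", CFG
        )
        assert np.max(np.abs(back - t)) < 1e-9

    def test_strictly_decreasing_with_slope(self):
        t1 = o.temperature_from_d18o(1.0, "Dorset", CFG)
        t2 = o.temperature_from_d18o(1.5, "Dorset", CFG)
        assert (t2 - t1) / 0.5 == pytest.approx(-1 / CFG.frac_b_mag)

    def test_unknown_location_raises(self):
        with pytest.raises(ConfigurationError, match="Atlantis"):
            o.temperature_from_d18o(1.0, "Atlantis", CFG)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=-20, max_value=20, **finite))
    def test_round_trip_property(self, d18o):
        t = o.temperature_from_d18o(d18o, "Dorset", CFG)
        assert o.d18o_from_temperature(t, "Dorset", CFG) == pytest.approx(
            d18o, abs=1e-9
        )


class TestRespirationProxy:
    @pytest.mark.parametrize(
        "oto,diet,expected",
        [
            (1.0, -19.0, 0.0),  # pure-DIC end-member
            (-19.0, -19.0, 1.0),  # pure-diet end-member
            (-4.0, -19.0, 0.25),  # (-5)/(-20)
        ],
    )
    def test_mass_balance_examples(self, oto, diet, expected):
        assert o.cresp_from_isotopes(oto, diet, CFG) == pytest.approx(expected)

    def test_inverse_examples(self):
        assert o.d13c_from_cresp(0.0, -19.0, CFG) == pytest.approx(1.0)
        assert o.d13c_from_cresp(0.25, -19.0, CFG) == pytest.approx(-4.0)

    def test_round_trip_grid_exact(self):
        c = np.linspace(0, 1, 11)
        back = o.cresp_from_isotopes(o.d13c_from_cresp(c, -19.0, CFG), -19.0, CFG)
        assert np.max(np.abs(back - c)) < 1e-9

    def test_zero_denominator_is_error(self):
        with pytest.raises(ComputationError):
            o.cresp_from_isotopes(-4.0, CFG.d13c_dic, CFG)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0, max_value=1, **finite),
        st.floats(min_value=-40, max_value=-5, **finite),
    )
    def test_end_member_containment(self, w, diet):
        # otolith d13C a convex combination of DIC and diet -> C_resp == w
        oto = w * diet + (1 - w) * CFG.d13c_dic
        assert o.cresp_from_isotopes(oto, diet, CFG) == pytest.approx(w, abs=1e-9)

    def test_epsilon_added_outside_the_ratio(self):
        cfg_eps = o.EnvCalibConfig(epsilon=0.1)
        base = o.cresp_from_isotopes(-4.0, -19.0, CFG)
        assert o.cresp_from_isotopes(-4.0, -19.0, cfg_eps) == pytest.approx(base + 0.1)


class TestFMRCalibration:
    @pytest.mark.parametrize(
        "cresp,expected,tol",
        [
            (0.041, 0.0, 1e-12),
            (0.2, 163.75, 0.01),
            (0.041 + 0.000971, 1.0, 1e-9),
        ],
    )
    def test_calibration_examples(self, cresp, expected, tol):
        assert o.fmr_from_cresp(cresp, CFG) == pytest.approx(expected, abs=tol)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=-0.5, max_value=1.5, **finite),
        st.floats(min_value=-0.5, max_value=0.5, **finite),
    )
    def test_affine_increments(self, c, delta):
        lhs = o.fmr_from_cresp(c + delta, CFG) - o.fmr_from_cresp(c, CFG)
        assert lhs == pytest.approx(delta / CFG.c1, rel=1e-9, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=-500, max_value=1500, **finite))
    def test_round_trip_property(self, fmr):
        assert o.fmr_from_cresp(o.cresp_from_fmr(fmr, CFG), CFG) == pytest.approx(
            fmr, abs=1e-9 * max(1, abs(fmr))
        )


class TestDietImputation:
    @staticmethod
    def frame(diets, species="X", location="Dorset"):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(diets))],
                "species": species,
                "location": location,
                "d13C_diet": diets,
            }
        )

    def test_mean_imputation(self):
        df, mask = o.impute_diet_d13c(self.frame([-18.0, -20.0, np.nan]), CFG)
        assert df["d13C_diet"].iloc[2] == pytest.approx(-19.0)
        assert mask.tolist() == [False, False, True]

    def test_no_missing_is_identity(self):
        base = self.frame([-18.0, -20.0])
        df, mask = o.impute_diet_d13c(base, CFG)
        pd.testing.assert_series_equal(df["d13C_diet"], base["d13C_diet"])
        assert not mask.any()

    def test_single_value_fills_whole_group(self):
        df, _ = o.impute_diet_d13c(self.frame([-17.0, np.nan, np.nan]), CFG)
        assert df["d13C_diet"].tolist() == [-17.0, -17.0, -17.0]

    def test_species_without_any_value_raises(self):
        df = self.frame([np.nan, np.nan], species="Y")
        with pytest.raises(DataError, match="Y"):
            o.impute_diet_d13c(df, CFG)

    def test_location_group_preferred_then_species_fallback(self):
        df = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "species": "X",
                "location": ["Dorset", "Dorset", "Skye", "Skye"],
                "d13C_diet": [-18.0, np.nan, np.nan, np.nan],
            }
        )
        out, _ = o.impute_diet_d13c(df, CFG)
        # Dorset missing -> Dorset mean; Skye has none -> species-wide mean
        assert out["d13C_diet"].tolist() == [-18.0, -18.0, -18.0, -18.0]
        flat = o.EnvCalibConfig(impute_by_location_first=False)
        df2 = df.assign(d13C_diet=[-18.0, -20.0, np.nan, np.nan])
        out2, _ = o.impute_diet_d13c(df2, flat)
        assert out2["d13C_diet"].iloc[2] == pytest.approx(-19.0)


class TestDeriveAll:
    def test_zero_noise_round_trip(self):
        from dataclasses import replace

        species, locations = o.default_params()
        quiet = [
            replace(s, temp_noise_sd_c=0.0, fmr_noise_sd_ln=0.0,
                    diet_d13c_sd=0.0, diet_missing_frac=0.0)
            for s in species
        ]
        cfg = o.simulation_config(locations, quiet)
        samples, truth = o.simulate_cohort(quiet, locations, seed=5, n_per_cell=20)
        derived, report = o.derive_all(samples, cfg)
        assert report["n_rejected"] == 0
        for col in ("temperature_C", "c_resp", "fmr_mgO2_kg_hr"):
            assert np.max(np.abs(derived[col] - truth[col])) < 1e-6

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["sample_id", "species", "location"])
        derived, report = o.derive_all(empty, CFG)
        assert len(derived) == 0 and report["n_input"] == 0

    def test_missing_d18o_flags_record_only(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "species": "X",
                "location": "Dorset",
                "body_mass_g": [10.0, 12.0],
                "d18O_oto": [np.nan, 1.018],
                "d13C_oto": [-4.0, -4.0],
                "d13C_diet": [-19.0, -19.0],
            }
        )
        derived, report = o.derive_all(df, CFG)
        assert np.isnan(derived["temperature_C"].iloc[0])
        assert "d18O_oto" in derived["reject_reason"].iloc[0]
        assert derived["temperature_C"].iloc[1] == pytest.approx(14.10, abs=0.01)
        assert derived["c_resp"].iloc[0] == pytest.approx(0.25)
        assert report["n_incomplete"] == 1

    def test_measured_mass_wins_over_length(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a"],
                "species": "X",
                "location": "Dorset",
                "total_length_cm": [10.0],
                "body_mass_g": [42.0],
                "d18O_oto": [1.018],
                "d13C_oto": [-4.0],
                "d13C_diet": [-19.0],
            }
        )
        derived, _ = o.derive_all(df, CFG)
        assert derived["body_mass_g"].iloc[0] == 42.0

    def test_no_size_information_rejects_record(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a"],
                "species": "X",
                "location": "Dorset",
                "d18O_oto": [1.018],
                "d13C_oto": [-4.0],
                "d13C_diet": [-19.0],
            }
        )
        derived, report = o.derive_all(df, CFG)
        assert bool(derived["flag_rejected"].iloc[0])
        assert report["n_rejected"] == 1

    def test_out_of_range_cresp_flagged_not_clipped(self):
        df = pd.DataFrame(
            {
                "sample_id": ["hot"],
                "species": "X",
                "location": "Dorset",
                "body_mass_g": [10.0],
                "d18O_oto": [1.0],
                "d13C_oto": [-25.0],  # beyond the diet end-member
                "d13C_diet": [-19.0],
            }
        )
        derived, _ = o.derive_all(df, CFG)
        assert derived["c_resp"].iloc[0] > 1
        assert bool(derived["flag_cresp_out_of_range"].iloc[0])
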