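"""Synthetic generator: design shape, determinism, noise calibration,
and exact invertibility through the gas mass balance."""

import numpy as np
import pandas as pd
import pytest

from sedch4 import agemodel, gascalc, synthdata
from sedch4.globalmodel import PUBLISHED_MODEL
from sedch4.synthdata import NoiseSpec, ReservoirSpec


class TestGenerateDesign:
    def test_default_design_reproduces_study_shape(self, noisy_tables):
        slices, truth, _ = noisy_tables
        assert len(slices) == 42
        assert (slices["slice_top_cm"] == 2.0).sum() == 17
        assert slices["core_id"].nunique() == 17
        assert slices["reservoir"].nunique() == 3
        # exactly one sub-surface slice per core, all 4 cm thick
        surf = slices[slices["slice_top_cm"] == 2.0]
        assert surf["core_id"].is_unique
        np.testing.assert_allclose(
            slices["slice_bottom_cm"] - slices["slice_top_cm"], 4.0)

    def test_minimal_single_slice_design(self):
        spec = ReservoirSpec("X", 2000, "2016-01-01", "test", (1.0, 2.0),
                             (0.1, 0.3), (0.5, 0.7), 1, 20.0, (1,))
        slices, truth = synthdata.generate_design([spec], NoiseSpec(seed=0))
        assert len(slices) == 1
        assert (slices["slice_top_cm"].iloc[0],
                slices["slice_bottom_cm"].iloc[0]) == (2.0, 6.0)

    def test_same_seed_is_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            noise = NoiseSpec(seed=99)
            slices, truth = synthdata.generate_design(noise=noise)
            vials = synthdata.generate_incubation(slices, truth, noise=noise)
            synthdata.write_outputs(slices, vials, truth, tmp_path / run, 99)
        for name in ("slices.csv", "vials.csv", "truth.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_different_seeds_differ(self):
        s1, _ = synthdata.generate_design(noise=NoiseSpec(seed=1))
        s2, _ = synthdata.generate_design(noise=NoiseSpec(seed=2))
        assert not s1["tc_pct_start"].equals(s2["tc_pct_start"])

    def test_chemistry_inside_configured_ranges_and_correlated(self, noisy_tables):
        slices, _, _ = noisy_tables
        by_res = {spec.name: spec for spec in synthdata.DEFAULT_RESERVOIRS}
        for res, grp in slices.groupby("reservoir"):
            spec = by_res[res]
            assert grp["tc_pct_start"].between(*spec.tc_range).all()
            assert grp["tn_pct_start"].between(*spec.tn_range).all()
        r = np.corrcoef(slices["tc_pct_start"], slices["tn_pct_start"])[0, 1]
        assert r > 0

    def test_overfull_core_rejected(self):
        spec = ReservoirSpec("X", 2000, "2016-01-01", "test", (1.0, 2.0),
                             (0.1, 0.3), (0.5, 0.7), 1, 20.0, (4,))
        with pytest.raises(ValueError, match="non-overlapping"):
            synthdata._slice_intervals(15.0, 4)
        del spec

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ReservoirSpec("X", 2020, "2016-01-01", "t", (1, 2), (0.1, 0.3),
                          (0.5, 0.7), 1, 20.0, (1,))
        with pytest.raises(ValueError):
            ReservoirSpec("X", 2000, "2016-01-01", "t", (2, 1), (0.1, 0.3),
                          (0.5, 0.7), 1, 20.0, (1,))
        with pytest.raises(ValueError):
            synthdata.TrueCoreParams("c", 1.0, -0.1, 0.5, 20.0, 2)


class TestGenerateIncubation:
    def test_row_count_is_design_product(self, noisy_tables):
        _, _, vials = noisy_tables
        assert len(vials) == 42 * 3 * 7  # slices x replicates x occasions

    def test_zero_noise_roundtrip_recovers_decay_curve(self, zero_noise_tables):
        """gascalc on noiseless generator output returns a*exp(-b*age)+c."""
        slices, truth, vials = zero_noise_tables
        rates = agemodel.annotate_rates(gascalc.compute_rates(vials, slices),
                                        slices)
        ch4 = rates[rates["gas"] == "ch4"].merge(truth, on="core_id")
        expect = (ch4["a_true"] * np.exp(-ch4["b_true"] * ch4["age_years"])
                  + ch4["c_true"])
        np.testing.assert_allclose(ch4["rate_c"], expect, rtol=1e-9)

    def test_roundtrip_property_on_random_parameter_draws(self):
        """Inversion identity holds across 100 random (a, b, c) draws."""
        rng = np.random.default_rng(31)
        spec = ReservoirSpec("X", 1990, "2016-01-01", "test", (1.0, 8.0),
                             (0.1, 0.6), (0.5, 0.7), 1, 40.0, (2,))
        noise = NoiseSpec(replicate_cv=0.0, ln_residual_sd=0.0, seed=0)
        slices, truth = synthdata.generate_design([spec], noise)
        draws = pd.DataFrame({
            "a_true": np.exp(rng.uniform(np.log(0.5), np.log(40), 100)),
            "b_true": rng.uniform(0.02, 1.5, 100),
            "c_true": rng.uniform(0.05, 2.0, 100)})
        for rec in draws.itertuples(index=False):
            t = truth.copy()
            t[["a_true", "b_true", "c_true"]] = (rec.a_true, rec.b_true,
                                                 rec.c_true)
            vials = synthdata.generate_incubation(slices, t, noise)
            rates = agemodel.annotate_rates(
                gascalc.compute_rates(vials, slices), slices)
            ch4 = rates[rates["gas"] == "ch4"]
            expect = (rec.a_true * np.exp(-rec.b_true * ch4["age_years"])
                      + rec.c_true)
            np.testing.assert_allclose(ch4["rate_c"], expect, rtol=1e-9)

    def test_replicate_cv_calibration_at_many_draws(self):
        """Empirical CV of the replicate noise factor within 5% of 8.6%."""
        rng = np.random.default_rng(17)
        cv = 0.086
        sigma2 = np.log1p(cv ** 2)
        draws = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), 10_000))
        emp_cv = draws.std(ddof=1) / draws.mean()
        assert emp_cv == pytest.approx(cv, rel=0.05)
        assert draws.mean() == pytest.approx(1.0, rel=0.01)

    def test_no_resampling_needed_at_default_noise(self, noisy_tables):
        _, _, vials = noisy_tables
        assert vials.attrs["n_resampled"] == 0
        assert (vials["ch4_ppm_end"] >= 0).all()


class TestRegressionDesign:
    def test_reproducible_table_of_requested_size(self):
        d1 = synthdata.generate_regression_design(764, seed=7)
        d2 = synthdata.generate_regression_design(764, seed=7)
        assert len(d1) == 764
        pd.testing.assert_frame_equal(d1, d2)

    def test_zero_noise_lies_on_model_surface(self):
        from sedch4.globalmodel import GlobalModel
        flat = GlobalModel(-0.59, 6.46, -0.99, -3.12, 0.0, 0.81, 764)
        df = synthdata.generate_regression_design(100, coeffs=flat, seed=8)
        np.testing.assert_allclose(
            df["ln_rate"], flat.ln_mean(df["age_years"], df["tn_pct"]),
            rtol=0, atol=1e-12)

    def test_residual_variance_matches_configuration(self):
        df = synthdata.generate_regression_design(100_000, seed=9)
        resid = df["ln_rate"] - PUBLISHED_MODEL.ln_mean(df["age_years"],
                                                    df["tn_pct"])
        assert resid.var(ddof=1) == pytest.approx(0.28, abs=0.01)

    def test_covariates_respect_ranges(self):
        df = synthdata.generate_regression_design(5000, seed=10)
        assert df["age_years"].between(1.0, 48.0).all()
        assert df["tn_pct"].between(0.1, 0.8).all()

    def test_nonpositive_age_range_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_regression_design(100, age_range=(0.0, 48.0))

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            synthdata.generate_regression_design(5)
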