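"""Wear indices: pristine baselines, the weighted tooth-loss index, and
the wear-force regression."""

import numpy as np
import pandas as pd
import pytest

from antcut.simulate import PopulationGenParams, gen_population
from antcut.wear import compute_wear, fit_pristine_baseline, wear_force_regression


def exact_callows(n=20, A=100.0, b=0.33):
    mass = np.geomspace(2.0, 45.0, n)
    return pd.DataFrame({
        "specimen_id": [f"c{i}" for i in range(n)],
        "body_mass_mg": mass,
        "group": "callow",
        "blade_um": 250.0 * mass**b,
        "T1_um": A * mass**b,
        "T2_um": 0.8 * A * mass**b,
    })


class TestPristineBaseline:
    def test_noiseless_allometry_recovered_exactly(self):
        df = exact_callows(A=100.0, b=0.33)
        base = fit_pristine_baseline(df)
        assert base.T1.intercept == pytest.approx(2.0, abs=1e-10)
        assert base.T1.slope == pytest.approx(0.33, abs=1e-10)
        assert base.T2.slope == pytest.approx(0.33, abs=1e-10)

    def test_constant_tooth_length_gives_zero_exponent(self):
        df = exact_callows()
        df["T1_um"] = 80.0
        df["T2_um"] = 60.0
        base = fit_pristine_baseline(df)
        assert base.T1.slope == pytest.approx(0.0, abs=1e-10)
        assert base.T1.predict(10.0) == pytest.approx(80.0)

    def test_forager_rows_rejected(self):
        df = exact_callows()
        df.loc[df.index[0], "group"] = "forager"
        with pytest.raises(ValueError):
            fit_pristine_baseline(df)

    def test_too_few_callows_rejected(self):
        with pytest.raises(ValueError):
            fit_pristine_baseline(exact_callows(n=2))

    def test_unmeasurable_teeth_dropped_with_count(self):
        df = exact_callows(n=10)
        df.loc[df.index[:3], "T2_um"] = np.nan
        base = fit_pristine_baseline(df)
        assert base.n_dropped == 3
        assert base.T1.n == 7

    def test_exponent_ci_covers_truth_in_most_replicates(self):
        hits = 0
        for rep in range(60):
            df = gen_population(PopulationGenParams(
                n_workers=40, group_mix=0.0, seed=500 + rep))
            base = fit_pristine_baseline(df)
            lo, hi = base.T2.ci_slope
            hits += lo <= 1.0 / 3.0 <= hi
        assert hits / 60 >= 0.90


class TestWearIndex:
    def test_pristine_observations_have_zero_wear(self):
        df = exact_callows()
        base = fit_pristine_baseline(df)
        out = compute_wear(df, base, alpha=1.0)
        np.testing.assert_allclose(out["W_um"], 0.0, atol=1e-9)
        np.testing.assert_allclose(out["W_star"], 0.0, atol=1e-12)

    def test_hand_evaluated_weighted_index(self):
        # dT1 = 10 um, dT2 = 5 um, alpha = 0.5 -> W = (5 + 0.5*10)/2 = 5
        callows = exact_callows()
        callows["T1_um"] = 100.0
        callows["T2_um"] = 50.0
        base = fit_pristine_baseline(callows)
        forager = pd.DataFrame({
            "specimen_id": ["f0"], "body_mass_mg": [10.0], "group": ["forager"],
            "blade_um": [500.0], "T1_um": [90.0], "T2_um": [45.0],
        })
        out = compute_wear(forager, base, alpha=0.5)
        assert out["W_um"].iloc[0] == pytest.approx(5.0, abs=1e-9)
        assert out["W_star"].iloc[0] == pytest.approx(5.0 / 50.0, abs=1e-9)

    def test_alpha_estimated_from_foragers_only(self):
        callows = exact_callows()
        callows["T1_um"] = 100.0
        callows["T2_um"] = 50.0
        base = fit_pristine_baseline(callows)
        foragers = pd.DataFrame({
            "specimen_id": ["f0", "f1"], "body_mass_mg": [10.0, 20.0],
            "group": ["forager", "forager"], "blade_um": [500.0, 500.0],
            "T1_um": [90.0, 80.0],   # dT1 = 10, 20 -> mean 15
            "T2_um": [44.0, 47.0],   # dT2 = 6, 3 -> mean 4.5
        })
        both = pd.concat([callows, foragers], ignore_index=True)
        out = compute_wear(both, base)
        assert out["alpha"].iloc[0] == pytest.approx(4.5 / 15.0)

    def test_zero_mean_first_tooth_loss_makes_alpha_undefined(self):
        callows = exact_callows()
        callows["T1_um"] = 100.0
        callows["T2_um"] = 50.0
        base = fit_pristine_baseline(callows)
        forager = pd.DataFrame({
            "specimen_id": ["f0"], "body_mass_mg": [10.0], "group": ["forager"],
            "blade_um": [500.0], "T1_um": [100.0], "T2_um": [45.0],
        })
        with pytest.raises(ValueError, match="alpha"):
            compute_wear(forager, base)

    def test_index_is_linear_in_tooth_losses(self):
        callows = exact_callows()
        callows["T1_um"] = 100.0
        callows["T2_um"] = 50.0
        base = fit_pristine_baseline(callows)

        def forager(dT1, dT2):
            return pd.DataFrame({
                "specimen_id": ["f"], "body_mass_mg": [10.0], "group": ["forager"],
                "blade_um": [500.0], "T1_um": [100.0 - dT1], "T2_um": [50.0 - dT2],
            })

        w1 = compute_wear(forager(4.0, 6.0), base, alpha=0.8)["W_um"].iloc[0]
        w2 = compute_wear(forager(8.0, 12.0), base, alpha=0.8)["W_um"].iloc[0]
        assert w2 == pytest.approx(2 * w1, rel=1e-12)

    def test_recovers_injected_forager_wear(self):
        # injected mean wear ~8 um; recovered mean W within 1 um
        p = PopulationGenParams(n_workers=120, group_mix=0.5, wear_mean=8.0,
                                wear_sd=5.0, morphometric_noise_sd=2.0, seed=42)
        df = gen_population(p)
        base = fit_pristine_baseline(df[df["group"] == "callow"])
        out = compute_wear(df, base)
        foragers = out[out["group"] == "forager"]
        assert foragers["W_um"].mean() == pytest.approx(
            foragers["true_wear_um"].mean(), abs=1.0)

    def test_callow_index_centres_on_zero_as_noise_vanishes(self):
        p = PopulationGenParams(n_workers=60, group_mix=0.5,
                                morphometric_noise_sd=0.0, seed=8)
        df = gen_population(p)
        base = fit_pristine_baseline(df[df["group"] == "callow"])
        out = compute_wear(df, base)
        callow_W = out.loc[out["group"] == "callow", "W_um"]
        assert np.abs(callow_W).max() < 1e-9


class TestWearForceRegression:
    def test_exact_line_recovers_slope(self):
        W = np.linspace(0, 30, 20)
        F = 31.0 + 2.09 * W
        fit = wear_force_regression(W, F)
        assert fit.slope == pytest.approx(2.09, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_force_has_ci_containing_zero(self, rng):
        W = np.linspace(0, 30, 40)
        F = 60.0 + rng.normal(0, 5.0, 40)
        fit = wear_force_regression(W, F)
        lo, hi = fit.ci_slope
        assert lo < 0 < hi

    def test_constant_wear_rejected(self):
        with pytest.raises(ValueError):
            wear_force_regression(np.full(5, 3.0), np.arange(5.0))

    def test_slope_ci_covers_generating_slope(self, rng):
        hits = 0
        for _ in range(60):
            W = rng.uniform(0, 25, 24)
            F = 30 + 3.7 * W + rng.normal(0, 15, 24)
            fit = wear_force_regression(W, F)
            hits += fit.ci_slope[0] <= 3.7 <= fit.ci_slope[1]
        assert hits / 60 >= 0.90
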