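"""Background subtraction, trapezoid AUC, ΔAUC dose-response, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest

from calproscreen.growth import (
    AUCResult,
    GrowthCurve,
    GrowthError,
    anova_tukey,
    auc_trapezoid,
    delta_auc,
    dose_response,
    subtract_background,
)
from calproscreen.simulate import GrowthSimParams, simulate_growth_plate
from calproscreen.tables import BLANK


def toy_table(cond_od=0.5, blank_od=0.1, times=(0.0, 0.5, 1.0)):
    rows = []
    for t in times:
        rows.append(dict(strain="s", protein="p", concentration=1.0,
                         replicate_bio=1, replicate_tech=1, well="W1",
                         time=t, od600=cond_od))
        rows.append(dict(strain=BLANK, protein="p", concentration=1.0,
                         replicate_bio=0, replicate_tech=1, well="B1",
                         time=t, od600=blank_od))
        rows.append(dict(strain="s", protein="p", concentration=0.0,
                         replicate_bio=1, replicate_tech=1, well="W0",
                         time=t, od600=cond_od))
        rows.append(dict(strain=BLANK, protein="p", concentration=0.0,
                         replicate_bio=0, replicate_tech=1, well="B0",
                         time=t, od600=blank_od))
    return pd.DataFrame(rows)


def curve(od, times=None, **kw):
    od = np.asarray(od, float)
    times = np.asarray(times if times is not None else np.arange(len(od)) * 0.25, float)
    defaults = dict(strain="s", protein="p", concentration=1.0, replicate_bio=1)
    defaults.update(kw)
    return GrowthCurve(times=times, od=od, **defaults)


class TestSubtractBackground:
    def test_constant_condition_minus_constant_blank(self):
        curves = subtract_background(toy_table(0.5, 0.1))
        treated = [c for c in curves if c.concentration == 1.0][0]
        assert np.allclose(treated.od, 0.4)

    def test_condition_equal_to_blank_is_zero(self):
        curves = subtract_background(toy_table(0.1, 0.1))
        assert all(np.allclose(c.od, 0.0) for c in curves)

    def test_missing_blank_named(self):
        table = toy_table()
        table = table[~((table["strain"] == BLANK) & (table["concentration"] == 1.0))]
        with pytest.raises(GrowthError, match="concentration=1.0"):
            subtract_background(table)

    def test_simulator_truth_recovered_within_noise(self):
        params = GrowthSimParams(seed=8, noise_sd=0.005, doses=(0.0, 50.0))
        table, truth = simulate_growth_plate(params)
        curves = subtract_background(table)
        for c in curves:
            signal = np.array(truth["noiseless_signal"][str(c.concentration)])
            # averaged over n_tech=3 wells minus blank mean: noise ~ sd
            assert np.abs(c.od - signal).max() < 6 * params.noise_sd

    def test_isolated_gap_interpolated_consecutive_rejected(self):
        table = toy_table(times=(0.0, 0.25, 0.5, 0.75, 1.0))
        one_gap = table.copy()
        mask = (one_gap["well"] == "W1") & (one_gap["time"] == 0.5)
        one_gap.loc[mask, "od600"] = np.nan
        curves = subtract_background(one_gap)
        treated = [c for c in curves if c.concentration == 1.0][0]
        assert np.allclose(treated.od, 0.4)  # linear fill of a flat series
        two_gaps = table.copy()
        mask2 = (two_gaps["well"] == "W1") & (two_gaps["time"].isin([0.25, 0.5]))
        two_gaps.loc[mask2, "od600"] = np.nan
        with pytest.raises(GrowthError, match="consecutive"):
            subtract_background(two_gaps)


class TestAUC:
    def test_constant_closed_form(self):
        t = np.arange(0, 13.01, 0.25)
        res = auc_trapezoid(curve(np.full(t.shape, 0.3), t))
        assert res.auc == pytest.approx(13 * 0.3)

    def test_linear_ramp_closed_form(self):
        t = np.arange(0, 13.01, 0.25)
        res = auc_trapezoid(curve(t / 13.0, t))
        assert res.auc == pytest.approx(6.5)

    def test_logistic_matches_analytic_integral_within_trapezoid_bound(self):
        params = GrowthSimParams(noise_sd=0.0)
        t = params.grid()
        y = params.signal(t, 0.0)
        res = auc_trapezoid(curve(y, t))
        exact = params.signal_auc_closed_form(0.0)
        # composite trapezoid error bound: (b-a) h^2 / 12 * max|f''| with
        # |f''| <= K r^2 / (6*sqrt(3)) for a logistic
        bound = 13.0 * 0.25**2 / 12.0 * params.K * params.r**2 / (6 * np.sqrt(3))
        assert abs(res.auc - exact) <= bound

    def test_linearity_on_shared_grid(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 13.01, 0.25)
        f, g = rng.normal(size=t.shape), rng.normal(size=t.shape)
        lhs = auc_trapezoid(curve(2.0 * f + 3.0 * g, t)).auc
        rhs = 2.0 * auc_trapezoid(curve(f, t)).auc + 3.0 * auc_trapezoid(curve(g, t)).auc
        assert lhs == pytest.approx(rhs)

    def test_window_subset_and_bad_window(self):
        t = np.arange(0, 13.01, 0.25)
        res = auc_trapezoid(curve(np.full(t.shape, 1.0), t), window=(2.0, 5.0))
        assert res.auc == pytest.approx(3.0)
        with pytest.raises(GrowthError, match="window"):
            auc_trapezoid(curve(np.full(t.shape, 1.0), t), window=(0.0, 14.0))


class TestDeltaAUC:
    def test_self_difference_zero_and_antisymmetry(self):
        t = np.arange(0, 13.01, 0.25)
        a = auc_trapezoid(curve(t / 13.0, t))
        b = auc_trapezoid(curve(np.full(t.shape, 0.2), t, concentration=0.0))
        assert delta_auc(a, a) == 0.0
        assert delta_auc(a, b) == -delta_auc(b, a)

    def test_strain_mismatch_rejected(self):
        t = np.arange(0, 13.01, 0.25)
        a = auc_trapezoid(curve(t, t, strain="s1"))
        b = auc_trapezoid(curve(t, t, strain="s2"))
        with pytest.raises(GrowthError, match="strain"):
            delta_auc(a, b)


class TestDoseResponse:
    def test_single_replicate_sem_zero_n_one(self):
        params = GrowthSimParams(seed=1, n_bio=1, n_tech=1, noise_sd=0.0,
                                 doses=(0.0, 50.0))
        table, _ = simulate_growth_plate(params)
        summary = dose_response(subtract_background(table))
        assert (summary["n"] == 1).all()
        assert (summary["sem"] == 0.0).all()

    def test_zero_effect_zero_noise_gives_zero_delta_auc(self):
        params = GrowthSimParams(seed=2, effect=0.0, noise_sd=0.0)
        table, _ = simulate_growth_plate(params)
        summary = dose_response(subtract_background(table))
        assert np.abs(summary["mean_delta_auc"]).max() < 1e-9

    def test_monotone_inhibition_at_zero_noise(self):
        params = GrowthSimParams(seed=3, noise_sd=0.0)  # Hill IC50 = 20 µM
        table, _ = simulate_growth_plate(params)
        summary = dose_response(subtract_background(table))
        by_dose = summary.sort_values("concentration")["mean_delta_auc"].to_numpy()
        assert np.all(np.diff(by_dose) < 0)  # strictly decreasing in dose

    def test_full_inhibition_equals_minus_control_auc(self):
        params = GrowthSimParams(seed=4, noise_sd=0.0, doses=(0.0, 10000.0))
        table, truth = simulate_growth_plate(params)
        summary = dose_response(subtract_background(table))
        top = summary[summary["concentration"] == 10000.0]["mean_delta_auc"].iloc[0]
        # treated curve flat at blank level: ΔAUC = −AUC(control signal)
        s = params.inhibition_multiplier(10000.0)
        assert s < 1e-4
        assert top == pytest.approx(-truth["control_auc"], rel=1e-3)

    def test_missing_control_replicate_rejected(self):
        params = GrowthSimParams(seed=5, doses=(0.0, 50.0), n_bio=2)
        table, _ = simulate_growth_plate(params)
        table = table[~((table["concentration"] == 0.0)
                        & (table["replicate_bio"] == 2))]
        with pytest.raises(GrowthError, match="control"):
            dose_response(subtract_background(table))

    def test_null_simulation_calibration(self):
        # no treatment effect: |mean ΔAUC| should stay within 4 SEM at every
        # dose in at least 95% of seeds
        ok = 0
        n_seeds = 200
        for seed in range(n_seeds):
            params = GrowthSimParams(
                seed=seed, effect=0.0, noise_sd=0.01,
                doses=(0.0, 25.0, 50.0), n_bio=8, n_tech=1,
            )
            table, _ = simulate_growth_plate(params)
            summary = dose_response(subtract_background(table))
            ok += bool(
                (summary["mean_delta_auc"].abs() <= 4 * summary["sem"]).all()
            )
        assert ok >= 0.95 * n_seeds


def one_way_f_oracle(groups):
    """Classical between/within mean-square ratio from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


class TestAnovaTukey:
    GROUPS = {
        "hCP": [-8.1, -7.9, -8.4],
        "s100a1": [0.6, 0.9, 0.2],
        "icn": [0.1, -0.2, 0.3],
    }

    def frame(self):
        rows = [
            {"strain": "s", "protein": p, "delta_auc": v}
            for p, vals in self.GROUPS.items()
            for v in vals
        ]
        return pd.DataFrame(rows)

    def test_one_way_f_matches_sums_of_squares_oracle(self):
        res = anova_tukey(self.frame(), design="one-way")
        f_oracle, _, _ = one_way_f_oracle(list(self.GROUPS.values()))
        f_fit = res.anova_table.loc["C(protein)", "F"]
        assert f_fit == pytest.approx(f_oracle, abs=1e-8)

    def test_tukey_matches_statsmodels_independent_route(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self.frame()
        res = anova_tukey(df, design="one-way")
        sm_res = pairwise_tukeyhsd(df["delta_auc"], df["protein"])
        sm_p = {
            tuple(sorted((g1, g2))): p
            for (g1, g2), p in zip(
                [(r[0], r[1]) for r in sm_res.summary().data[1:]],
                sm_res.pvalues,
            )
        }
        for _, row in res.comparisons.iterrows():
            key = tuple(sorted((row["group1"], row["group2"])))
            assert row["p_adj"] == pytest.approx(sm_p[key], abs=1e-8)

    def test_two_way_additive_uses_both_factors(self):
        rng = np.random.default_rng(9)
        rows = []
        strain_effect = {"s1": 0.0, "s2": -1.0}
        protein_effect = {"hCP": -8.0, "icn": 0.0, "s100w": 0.5}
        for strain, se in strain_effect.items():
            for protein, pe in protein_effect.items():
                for _ in range(3):
                    rows.append(
                        {"strain": strain, "protein": protein,
                         "delta_auc": se + pe + rng.normal(0, 0.1)}
                    )
        res = anova_tukey(pd.DataFrame(rows), design="two-way")
        assert res.anova_table.loc["C(protein)", "PR(>F)"] < 1e-6
        assert res.anova_table.loc["C(strain)", "PR(>F)"] < 1e-6
        assert len(res.comparisons) == 3  # all unordered protein pairs

    def test_identical_observations_rejected(self):
        df = pd.DataFrame(
            [{"strain": "s", "protein": p, "delta_auc": 1.0}
             for p in ("a", "a", "b", "b")]
        )
        with pytest.raises(GrowthError, match="residual variance"):
            anova_tukey(df, design="one-way")

    def test_single_observation_per_protein_rejected(self):
        df = pd.DataFrame(
            [{"strain": "s", "protein": "a", "delta_auc": 1.0},
             {"strain": "s", "protein": "a", "delta_auc": 2.0},
             {"strain": "s", "protein": "b", "delta_auc": 3.0}]
        )
        with pytest.raises(GrowthError, match="single observation"):
            anova_tukey(df)
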