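"""Mixed-model and model-selection layer: degenerate exactness, contrast
combinatorics, subset enumeration, adjusted R^2 and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coralvar.inference import (
    ENV_PREDICTORS,
    LMMSpec,
    adjusted_r2,
    exhaustive_subset_selection,
    fit_repeated_lmm,
    posthoc_contrasts,
    residual_diagnostics,
    transplant_spec,
)


def _balanced_rates(rng, stations=("A", "F", "Es", "Ed"), n_per_cell=4,
                    station_means=None, season_effects=None,
                    specimen_sd=0.1, residual_sd=0.15, transplant_effect=0.0):
    station_means = station_means or {s: 1.0 for s in stations}
    season_effects = season_effects or {"summer": 0.1, "autumn": 0.05, "winter": 0.0}
    rows, sid = [], 0
    for st in stations:
        for tr in ("native", "novel"):
            for _ in range(n_per_cell):
                sid += 1
                u = rng.normal(0.0, specimen_sd)
                for season, eff in season_effects.items():
                    g = (
                        station_means[st]
                        + eff
                        + (transplant_effect if tr == "novel" else 0.0)
                        + u
                        + rng.normal(0.0, residual_sd)
                    )
                    rows.append(
                        dict(
                            specimen_id=f"s{sid}",
                            station=st,
                            transplant=tr,
                            season=season,
                            calcification_g=g,
                        )
                    )
    return pd.DataFrame(rows)


class TestRepeatedLMM:
    def test_degenerate_data_recovers_cell_means(self, rng):
        """With zero specimen variance and zero noise, fitted effects
        reproduce the cell means exactly."""
        df = _balanced_rates(rng, specimen_sd=0.0, residual_sd=0.0,
                             station_means={"A": 0.4, "F": 0.8, "Es": 0.5, "Ed": 1.0})
        res = fit_repeated_lmm(
            df, LMMSpec("calcification_g", ("season", "station"))
        )
        cell = df.groupby(["season", "station"])["calcification_g"].mean()
        # additive design: the A/summer cell is intercept + summer + A effects
        fe = res.fixed_effects["estimate"]
        pred_a_summer = (
            fe["Intercept"]
            + fe.get("C(season)[T.summer]", 0.0)
        )
        assert pred_a_summer == pytest.approx(cell[("summer", "A")], abs=1e-8)

    def test_matches_ols_on_balanced_design(self, rng):
        """For balanced data the GLS fixed effects equal OLS estimates."""
        import statsmodels.formula.api as smf

        df = _balanced_rates(rng)
        res = fit_repeated_lmm(df, transplant_spec())
        ols = smf.ols(
            "calcification_g ~ C(season) + C(station) + C(station):C(transplant)", df
        ).fit()
        assert np.allclose(
            res.fixed_effects["estimate"].to_numpy(), ols.params.to_numpy(), atol=1e-6
        )

    def test_requires_repeated_measures(self, rng):
        df = _balanced_rates(rng)
        single = df[df["season"] == "summer"]
        with pytest.raises(ValueError, match="repeated"):
            fit_repeated_lmm(single, transplant_spec())

    def test_singular_design_rejected(self, rng):
        df = _balanced_rates(rng)
        df = df.assign(clone=df["station"])
        with pytest.raises(ValueError, match="singular"):
            fit_repeated_lmm(
                df, LMMSpec("calcification_g", ("season", "station", "clone"))
            )

    def test_detects_depth_effect(self, rng):
        """A 2x station contrast is flagged by the station term."""
        df = _balanced_rates(
            rng, station_means={"A": 0.5, "F": 0.5, "Es": 0.5, "Ed": 1.0}
        )
        res = fit_repeated_lmm(df, transplant_spec())
        assert res.term_tests.loc["C(station)", "p"] < 0.001

    def test_type_one_error_calibrated(self):
        """Null transplant effect: rejection near alpha over seeded reps."""
        rej = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            df = _balanced_rates(rng, transplant_effect=0.0)
            res = fit_repeated_lmm(df, transplant_spec())
            rej += res.term_tests.loc["C(station):C(transplant)", "p"] < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.07)


class TestContrasts:
    def test_two_level_factor_single_contrast(self, rng):
        df = _balanced_rates(rng, stations=("A", "F"))
        res = fit_repeated_lmm(
            df, LMMSpec("calcification_g", ("season", "station"))
        )
        table = posthoc_contrasts(res, "station")
        assert len(table) == 1
        fe = res.fixed_effects["estimate"]
        assert abs(table["estimate"].iloc[0]) == pytest.approx(
            abs(fe["C(station)[T.F]"]), abs=1e-9
        )

    def test_pairwise_count(self, rng):
        """k levels yield k(k-1)/2 contrasts (6 stations -> 15)."""
        df = _balanced_rates(rng, stations=("A", "B", "C", "D", "Es", "F"))
        res = fit_repeated_lmm(
            df, LMMSpec("calcification_g", ("season", "station"))
        )
        assert len(posthoc_contrasts(res, "station")) == 15
        assert len(posthoc_contrasts(res, "season")) == 3

    def test_sign_pattern_follows_true_ordering(self, rng):
        """Monotone true station means produce monotone significant contrasts."""
        means = {"A": 0.3, "B": 0.6, "C": 0.9, "D": 1.2}
        df = _balanced_rates(rng, stations=tuple(means), station_means=means,
                             n_per_cell=6)
        res = fit_repeated_lmm(
            df, LMMSpec("calcification_g", ("season", "station"))
        )
        table = posthoc_contrasts(res, "station")
        sig = table[table["p_adj"] < 0.05]
        for row in sig.itertuples():
            assert np.sign(row.estimate) == np.sign(
                means[row.level_a] - means[row.level_b]
            )

    def test_unknown_factor_rejected(self, rng):
        df = _balanced_rates(rng)
        res = fit_repeated_lmm(df, transplant_spec())
        with pytest.raises(KeyError):
            posthoc_contrasts(res, "depth")

    def test_holm_adjustment_bounded(self, rng):
        df = _balanced_rates(rng)
        res = fit_repeated_lmm(df, transplant_spec())
        table = posthoc_contrasts(res, "station", adjust="holm")
        assert ((table["p_adj"] >= table["p_raw"] - 1e-12) & (table["p_adj"] <= 1)).all()


class TestSubsetSelection:
    def _table(self, rng, n=21):
        x = pd.DataFrame(rng.normal(size=(n, 6)), columns=list(ENV_PREDICTORS))
        return x

    def test_enumeration_exhaustive_and_unique(self, rng):
        df = self._table(rng)
        df["calcification_g"] = rng.normal(size=len(df))
        sel = exhaustive_subset_selection(df, "calcification_g")
        subsets = list(sel.table["subset"])
        assert len(subsets) == 63
        assert len(set(subsets)) == 63

    def test_dominant_signal_wins(self, rng):
        df = self._table(rng)
        df["calcification_g"] = 2.0 + 1.5 * df["mean_temp_C"] + rng.normal(
            0, 0.01, len(df)
        )
        sel = exhaustive_subset_selection(df, "calcification_g")
        assert sel.best_model == ("mean_temp_C",)

    def test_weights_and_delta_invariants(self, rng):
        df = self._table(rng)
        df["calcification_g"] = rng.normal(size=len(df))
        sel = exhaustive_subset_selection(df, "calcification_g")
        assert sel.table["delta"].iloc[0] == 0.0
        assert sel.table["weight"].sum() == pytest.approx(1.0)
        assert sel.table["delta"].is_monotonic_increasing

    def test_nested_equal_likelihood_prefers_smaller(self, rng):
        """A redundant copy of the winning predictor ranks strictly worse."""
        df = self._table(rng)
        df["ph_total"] = df["mean_temp_C"]  # exact duplicate
        df["calcification_g"] = 1.0 + df["mean_temp_C"] + rng.normal(0, 0.05, len(df))
        sel = exhaustive_subset_selection(df, "calcification_g")
        tab = sel.table.set_index("subset")
        single = tab.loc[[("mean_temp_C",)]].iloc[0]
        pair = tab.loc[[("mean_temp_C", "ph_total")]].iloc[0]
        assert single["aicc"] < pair["aicc"]

    def test_small_sample_subsets_skipped(self, rng):
        df = self._table(rng, n=7)
        df["calcification_g"] = rng.normal(size=len(df))
        with pytest.warns(UserWarning, match="skipped"):
            sel = exhaustive_subset_selection(df, "calcification_g")
        assert sel.table["n_predictors"].max() < 6


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 20, 2) == pytest.approx(1.0)

    def test_intercept_only(self):
        assert adjusted_r2(0.0, 20, 0) == pytest.approx(0.0)

    def test_undefined_for_saturated_fit(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, 4, 3)

    def test_null_simulation_unbiased(self):
        """Pure-noise regressions average to adjusted R^2 near zero."""
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(1000):
            x = rng.normal(size=(20, 2))
            y = rng.normal(size=20)
            xx = np.column_stack([np.ones(20), x])
            beta, *_ = np.linalg.lstsq(xx, y, rcond=None)
            rss = np.sum((y - xx @ beta) ** 2)
            tss = np.sum((y - y.mean()) ** 2)
            vals.append(adjusted_r2(1 - rss / tss, 20, 2))
        assert abs(np.mean(vals)) < 0.02


class TestDiagnostics:
    def test_normal_null_calibration(self):
        """Normal residuals: the KS screen rejects near alpha."""
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            out = residual_diagnostics(rng.normal(size=200))
            rej += out["ks_p"] < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.05)

    def test_exponential_power(self):
        """Exponential residuals at n=200 are rejected in >=90% of reps."""
        rej = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(4000 + rep)
            out = residual_diagnostics(rng.exponential(size=200))
            rej += out["ks_p"] < 0.05
        assert rej / n_rep >= 0.9

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            residual_diagnostics(np.ones(50))
        with pytest.raises(ValueError, match="at least 3"):
            residual_diagnostics(np.array([0.1, -0.1]))

    def test_heteroscedasticity_detected(self, rng):
        x = np.linspace(0, 1, 300)
        resid = rng.normal(size=300) * (0.1 + 2 * x)
        out = residual_diagnostics(resid, exog=x)
        assert out["bp_p"] < 0.01

    def test_shapiro_on_response(self, rng):
        out = residual_diagnostics(rng.normal(size=50), response=rng.exponential(size=50))
        assert out["shapiro_p"] < 0.05
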