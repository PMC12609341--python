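"""Partialling-out DML: cross-fitting, orthogonal score, inference."""

import numpy as np
import pandas as pd
import pytest

from climres import SyntheticConfig, generate_panel
from climres.dml import (
    DMLConfig,
    LearnerSpec,
    PanelDML,
    crossfit_predict,
    dml_multi_treatment,
    dml_plr,
    encode_fixed_effects,
    make_interaction,
)
from climres.panel_ops import CONTROLS

RIDGE = LearnerSpec(kind="ridge_linear", ridge_alpha=1e-8)
MEAN = LearnerSpec(kind="mean_only")
RF25 = LearnerSpec(n_trees=25)


def _fast_cfg(**kw):
    base = dict(n_folds=5, n_repetitions=1, learner=RIDGE, fe_mode="none", seed=0)
    base.update(kw)
    return DMLConfig(**base)


class TestCrossfit:
    def test_mean_only_predictions_are_complement_means(self):
        y = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        folds = np.array([0, 0, 0, 1, 1, 1])
        preds = crossfit_predict(MEAN, np.zeros((6, 1)), y, folds)
        assert np.allclose(preds[:3], 20.0)  # trained on fold 1
        assert np.allclose(preds[3:], 2.0)  # trained on fold 0

    def test_ridge_recovers_exact_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = X[:, 0]
        folds = np.arange(60) % 5
        preds = crossfit_predict(RIDGE, X, y, folds)
        assert np.allclose(preds, y, atol=1e-6)

    def test_row_permutation_with_matched_folds_is_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        folds = np.arange(40) % 4
        base = crossfit_predict(RIDGE, X, y, folds, seed=7)
        perm = rng.permutation(40)
        permuted = crossfit_predict(RIDGE, X[perm], y[perm], folds[perm], seed=7)
        assert np.allclose(base[perm], permuted)

    def test_tiny_training_complement_fails(self):
        y = np.array([1.0, 2.0, 3.0])
        folds = np.array([0, 0, 1])
        with pytest.raises(ValueError, match="training samples"):
            crossfit_predict(MEAN, np.zeros((3, 1)), y, folds)


class TestFixedEffectEncoding:
    def test_two_way_appends_29_plus_11_dummies(self, clean_panel):
        df, _ = clean_panel
        base = encode_fixed_effects(df, "none")
        out = encode_fixed_effects(df, "two_way")
        assert out.shape[1] - base.shape[1] == 29 + 11

    def test_none_is_identity_on_controls(self, clean_panel):
        df, _ = clean_panel
        out = encode_fixed_effects(df, "none")
        pd.testing.assert_frame_equal(out, df[list(CONTROLS)])

    def test_time_location_interaction_with_two_groups_gives_23_dummies(self, clean_panel):
        df, _ = clean_panel
        out = encode_fixed_effects(df, "time_location_interaction")
        assert out.shape[1] - len(CONTROLS) == 2 * 12 - 1

    @pytest.mark.parametrize("mode,extra", [("time", 11), ("unit", 29)])
    def test_one_way_dummy_counts(self, clean_panel, mode, extra):
        df, _ = clean_panel
        out = encode_fixed_effects(df, mode)
        assert out.shape[1] - len(CONTROLS) == extra

    def test_unknown_mode_fails(self, clean_panel):
        df, _ = clean_panel
        with pytest.raises(ValueError, match="fe_mode"):
            encode_fixed_effects(df, "per_capita")


def _six_point_toy():
    """Printed 6-point set: two units, three years, no nuisance structure."""
    return pd.DataFrame(
        {
            "unit": ["A", "A", "A", "B", "B", "B"],
            "year": [2011, 2012, 2013, 2011, 2012, 2013],
            "y": [1.0, 2.0, 4.0, 3.0, 5.0, 8.0],
            "d": [0.0, 1.0, 2.0, 1.0, 3.0, 4.0],
            "x1": [0.0] * 6,
        }
    )


class TestHandOracle:
    def test_mean_only_single_split_matches_hand_arithmetic(self):
        """With mean-only learners and one fixed fold pair, theta equals the
        hand-computed ratio sum(V*(y - gbar)) / sum(V*d), where gbar and the
        treatment mean come from the opposite fold."""
        df = _six_point_toy()
        folds = np.array([0, 1, 0, 1, 0, 1])
        y = df["y"].to_numpy()
        d = df["d"].to_numpy()
        # independent hand computation with plain loops
        g_hat = np.empty(6)
        m_hat = np.empty(6)
        for i in range(6):
            other = folds != folds[i]
            g_hat[i] = y[other].mean()
            m_hat[i] = d[other].mean()
        v = d - m_hat
        theta_hand = float(np.sum(v * (y - g_hat)) / np.sum(v * d))

        res = dml_plr(
            df,
            outcome="y",
            treatment="d",
            controls=["x1"],
            config=_fast_cfg(learner=MEAN, n_folds=2),
            fold_assignment=folds,
        )
        assert float(res.theta.iloc[0]) == pytest.approx(theta_hand, abs=1e-12)

    def test_score_mean_is_zero_at_the_estimate(self):
        df = _six_point_toy()
        res = dml_plr(
            df,
            outcome="y",
            treatment="d",
            controls=["x1"],
            config=_fast_cfg(learner=MEAN, n_folds=2),
            fold_assignment=np.array([0, 1, 0, 1, 0, 1]),
        )
        assert res.residual_diagnostics["max_abs_score_mean"] < 1e-10


class TestAgainstOLS:
    def test_unconfounded_linear_panel_matches_ols_slope(self):
        """No confounding + linear DGP: DML with a ridge learner agrees with
        the full-sample OLS slope (Frisch-Waugh logic) within 0.01."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = SyntheticConfig(
            seed=11, confounding_scale=0.0, nuisance_form="linear",
            theta_interaction=0.0, missing_rate=0.0,
        )
        panel, _ = generate_panel(cfg)
        df = panel.frame
        res = dml_plr(df, treatment="TEMP", config=_fast_cfg(seed=3))
        X = sm.add_constant(df[["TEMP", *CONTROLS]].astype(float))
        ols = sm.OLS(df["FASCR"].to_numpy(), X).fit().params["TEMP"]
        assert float(res.theta.iloc[0]) == pytest.approx(ols, abs=0.01)


class TestRecovery:
    def test_temp_estimate_within_3_se_of_truth(self, clean_panel):
        df, truth = clean_panel
        res = dml_plr(df, treatment="TEMP", config=_fast_cfg(learner=RF25, seed=5))
        th, se = float(res.theta.iloc[0]), float(res.se.iloc[0])
        assert abs(th - truth.theta_by_treatment["TEMP"]) < 3 * se

    def test_rain_estimate_within_3_se_of_truth(self, clean_panel):
        df, truth = clean_panel
        res = dml_plr(df, treatment="RAIN", config=_fast_cfg(learner=RF25, seed=6))
        th, se = float(res.theta.iloc[0]), float(res.se.iloc[0])
        assert abs(th - truth.theta_by_treatment["RAIN"]) < 3 * se

    def test_repeated_splitting_median_aggregation(self, clean_panel):
        df, truth = clean_panel
        res = dml_plr(df, treatment="TEMP", config=_fast_cfg(n_repetitions=5, seed=7))
        assert res.per_rep_thetas.shape == (5, 1)
        assert float(res.theta.iloc[0]) == np.median(res.per_rep_thetas.iloc[:, 0])
        # aggregated variance is at least the per-repetition dispersion floor
        assert float(res.se.iloc[0]) > 0

    def test_t_stat_consistent_with_theta_and_se(self, clean_panel):
        df, _ = clean_panel
        res = dml_plr(df, treatment="TEMP", config=_fast_cfg(seed=8))
        assert float(res.t_stat.iloc[0]) == pytest.approx(
            float(res.theta.iloc[0]) / float(res.se.iloc[0]), abs=1e-10
        )


class TestModeration:
    def test_three_coefficient_rows(self, clean_panel):
        df, _ = clean_panel
        mdf, iname = make_interaction(df, "SID", "TEMP")
        res = dml_multi_treatment(
            mdf, treatments=("TEMP", "SID", iname), config=_fast_cfg(seed=9)
        )
        assert res.theta.index.tolist() == ["TEMP", "SID", "SID_x_TEMP"]
        assert res.to_frame().shape[0] == 3

    def test_interaction_recovery_within_3_se(self, clean_panel):
        df, truth = clean_panel
        mdf, iname = make_interaction(df, "SID", "TEMP")
        res = dml_multi_treatment(
            mdf, treatments=("TEMP", "SID", iname), config=_fast_cfg(learner=RF25, seed=10)
        )
        est, se = float(res.theta[iname]), float(res.se[iname])
        assert est > 0
        assert abs(est - truth.theta_by_treatment["SID_x_TEMP"]) < 3 * se

    def test_null_moderation_ci_covers_zero_in_at_least_90pct_of_seeds(self):
        """Size check: with zero true moderation the interaction CI covers 0."""
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            panel, _ = generate_panel(
                SyntheticConfig(seed=300 + s, theta_interaction=0.0, missing_rate=0.0)
            )
            mdf, iname = make_interaction(panel.frame, "SID", "TEMP")
            res = dml_multi_treatment(
                mdf, treatments=("TEMP", "SID", iname), config=_fast_cfg(seed=s)
            )
            lo = float(res.theta[iname]) - 1.96 * float(res.se[iname])
            hi = float(res.theta[iname]) + 1.96 * float(res.se[iname])
            hits += lo <= 0.0 <= hi
        assert hits / n_seeds >= 0.90

    def test_uncentered_interaction_option(self, clean_panel):
        df, _ = clean_panel
        raw, name = make_interaction(df, "SID", "TEMP", center=False)
        assert np.allclose(raw[name], df["SID"] * df["TEMP"])

    def test_collinear_treatments_fail_naming_columns(self, clean_panel):
        df, _ = clean_panel
        df = df.copy()
        df["TEMP2"] = df["TEMP"]
        with pytest.raises(ValueError, match="rank deficient"):
            dml_multi_treatment(df, treatments=("TEMP", "TEMP2"), config=_fast_cfg())


class TestFailureModes:
    def test_treatment_explained_by_controls_is_not_identified(self, clean_panel):
        df, _ = clean_panel
        df = df.copy()
        df["D"] = df["UL"]  # treatment identical to a control
        with pytest.raises(ValueError, match="identif"):
            dml_plr(df, treatment="D", config=_fast_cfg())

    def test_missing_values_rejected_before_estimation(self, default_panel):
        df, _ = default_panel
        df = df.copy()
        df.loc[0, "TEMP"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            PanelDML(df, treatments="TEMP")

    def test_even_repetition_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            DMLConfig(n_repetitions=2).validate()

    def test_determinism_with_fixed_seed(self, clean_panel):
        df, _ = clean_panel
        r1 = dml_plr(df, treatment="TEMP", config=_fast_cfg(learner=RF25, seed=12))
        r2 = dml_plr(df, treatment="TEMP", config=_fast_cfg(learner=RF25, seed=12))
        assert float(r1.theta.iloc[0]) == float(r2.theta.iloc[0])
        assert float(r1.se.iloc[0]) == float(r2.se.iloc[0])
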