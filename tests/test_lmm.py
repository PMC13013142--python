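import math

import numpy as np
import pandas as pd
import pytest

from menzerath import (
    LmmSpec,
    SizeDistribution,
    SyntheticConfig,
    TrialConfig,
    fit_accuracy_model,
    fit_group_interaction,
    fit_menzerath,
    simulate_call_table,
    simulate_trials,
    trained_crow_preset,
)
from menzerath.data_io import CallTable

from conftest import make_table


@pytest.fixture(scope="module")
def small_crossed_table():
    cfg = trained_crow_preset(beta1=-0.08, beta2=0.05, sequences_per_individual=80, seed=7)
    return simulate_call_table(cfg)


class TestAgainstLme4Reference:
    """Frozen reference values computed with R lme4 (lmer, nloptwrap) on the
    identical seeded table: log(duration) ~ log(size) + position +
    (1|sequence) + (1|individual) + (1|position category)."""

    def test_reml_estimates_and_se(self, small_crossed_table):
        res = fit_menzerath(small_crossed_table, LmmSpec(reml=True))
        ref = {
            "intercept": (-1.6994090, 0.0477844),
            "log_seq_size": (-0.0783414, 0.0342327),
            "position": (0.0740858, 0.0172265),
        }
        for name, (est, se) in ref.items():
            assert res.coef(name) == pytest.approx(est, abs=2e-5)
            assert res.se(name) == pytest.approx(se, abs=2e-5)

    def test_reml_variance_components(self, small_crossed_table):
        res = fit_menzerath(small_crossed_table, LmmSpec(reml=True))
        assert res.variance_components["sequence"] == pytest.approx(0.012236932, abs=2e-5)
        assert res.variance_components["position_cat"] == pytest.approx(0.000635154, abs=2e-5)
        assert res.variance_components["individual"] == pytest.approx(0.0, abs=2e-5)
        assert res.residual_var == pytest.approx(0.077912759, abs=2e-5)

    def test_ml_estimates_and_loglik(self, small_crossed_table):
        res = fit_menzerath(small_crossed_table, LmmSpec(reml=False))
        assert res.coef("log_seq_size") == pytest.approx(-0.0795073, abs=2e-5)
        assert res.coef("position") == pytest.approx(0.0737988, abs=2e-5)
        assert res.loglik == pytest.approx(-127.9566, abs=2e-3)


def test_single_random_intercept_matches_statsmodels(small_crossed_table):
    """Dual route: the sparse solver vs statsmodels MixedLM on the
    sequence-intercept-only submodel."""
    sm = pytest.importorskip("statsmodels.formula.api")
    from menzerath.lmm import RandomTerm, fit_lmm_core

    df = small_crossed_table.with_sizes()
    df["log_dur"] = np.log(df["duration_s"])
    df["log_size"] = np.log(df["seq_size"])
    ref = sm.mixedlm("log_dur ~ log_size + position", df, groups=df["sequence_id"]).fit(reml=True)

    y = df["log_dur"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["log_size"], df["position"]])
    codes, lvls = pd.factorize(df["sequence_id"])
    sol, _, _, conv = fit_lmm_core(y, X, ["intercept", "log_size", "position"],
                                   [RandomTerm("sequence", codes, len(lvls))], reml=True)
    assert conv
    np.testing.assert_allclose(sol["beta"], ref.fe_params.to_numpy(), atol=1e-5)
    # MixedLM's default optimizer converges less tightly than the sparse
    # profiled criterion; SEs agree to a fraction of a percent
    np.testing.assert_allclose(np.sqrt(np.diag(sol["cov_beta"])), ref.bse_fe.to_numpy(), rtol=5e-3)


def test_constant_durations_give_zero_slopes_and_log_intercept():
    table = make_table({f"s{i}": [0.5] * (1 + i % 3) for i in range(12)})
    res = fit_menzerath(table)
    assert res.coef("log_seq_size") == pytest.approx(0.0, abs=1e-10)
    assert res.coef("position") == pytest.approx(0.0, abs=1e-10)
    assert res.coef("intercept") == pytest.approx(math.log(0.5), abs=1e-10)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.variance_components.values())


def test_noise_free_fit_recovers_generating_effects_exactly():
    cfg = SyntheticConfig(beta0=-1.5, beta1=-0.07, beta2=0.04,
                          sigma_seq=0, sigma_ind=0, sigma_pos=0, sigma_eps=0,
                          n_individuals=2, sequences_per_individual=30, seed=5)
    res = fit_menzerath(simulate_call_table(cfg))
    assert res.coef("intercept") == pytest.approx(-1.5, rel=1e-9)
    assert res.coef("log_seq_size") == pytest.approx(-0.07, rel=1e-9)
    assert res.coef("position") == pytest.approx(0.04, rel=1e-9)


def test_synthetic_refit_within_confidence_interval(small_crossed_table):
    res = fit_menzerath(small_crossed_table)
    lo, hi = res.conf_int("log_seq_size")
    assert lo < -0.08 < hi
    lo, hi = res.conf_int("position")
    assert lo < 0.05 < hi


def test_scale_equivariance(small_crossed_table):
    """Rescaling durations shifts only the intercept, by log of the factor."""
    res = fit_menzerath(small_crossed_table)
    scaled_df = small_crossed_table.df.copy()
    scaled_df["duration_s"] *= 10.0
    res10 = fit_menzerath(CallTable(scaled_df))
    assert res10.coef("intercept") - res.coef("intercept") == pytest.approx(math.log(10), abs=1e-4)
    for name in ("log_seq_size", "position"):
        assert res10.coef(name) == pytest.approx(res.coef(name), abs=1e-4)
        assert res10.fixed_effects[name].t == pytest.approx(res.fixed_effects[name].t, rel=1e-3)


def test_row_order_invariance(small_crossed_table):
    res = fit_menzerath(small_crossed_table)
    shuffled = small_crossed_table.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res2 = fit_menzerath(CallTable(shuffled))
    for name in ("intercept", "log_seq_size", "position"):
        assert res2.coef(name) == pytest.approx(res.coef(name), abs=1e-5)


def test_exclude_singles_changes_sample(small_crossed_table):
    res = fit_menzerath(small_crossed_table, LmmSpec(include_singles=False))
    full = fit_menzerath(small_crossed_table)
    assert res.n_obs < full.n_obs
    assert res.n_sequences == int((small_crossed_table.sequence_sizes() >= 2).sum())


def test_single_individual_drops_random_effect_with_warning():
    cfg = trained_crow_preset(n_individuals=1, sequences_per_individual=60, seed=3)
    res = fit_menzerath(simulate_call_table(cfg))
    assert "individual" not in res.variance_components
    assert any("individual" in w for w in res.warnings)


def test_single_size_table_rejected():
    table = make_table({f"s{i}": [0.2, 0.3] for i in range(5)})
    with pytest.raises(ValueError, match="distinct sequence sizes"):
        fit_menzerath(table)


class TestGroupInteraction:
    def test_duplicated_table_gives_zero_interactions(self, small_crossed_table):
        df_b = small_crossed_table.df.copy()
        df_b["context"] = "other"
        res = fit_group_interaction(small_crossed_table, CallTable(df_b), "context")
        assert res.coef("context:log_seq_size") == pytest.approx(0.0, abs=1e-6)
        assert res.coef("context:position") == pytest.approx(0.0, abs=1e-6)
        assert res.coef("context") == pytest.approx(0.0, abs=1e-6)

    def test_identical_labels_rejected(self, small_crossed_table):
        with pytest.raises(ValueError, match="distinct"):
            fit_group_interaction(small_crossed_table, small_crossed_table)

    def test_interaction_recovers_generating_slope_difference(self):
        delta = -0.25
        a = simulate_call_table(trained_crow_preset(
            beta1=-0.05, sequences_per_individual=400, seed=21, context="ctx_a"))
        b = simulate_call_table(trained_crow_preset(
            beta1=-0.05 + delta, sequences_per_individual=400, seed=22, context="ctx_b"))
        res = fit_group_interaction(a, b, "context")
        est = res.coef("context:log_seq_size")
        se = res.se("context:log_seq_size")
        assert est - 1.96 * se < delta < est + 1.96 * se


class TestAccuracyModel:
    def test_against_lme4_reference(self):
        """Frozen lme4 values for accuracy ~ cue + (1|p) + (0+cue|p) on the
        identical seeded trial table."""
        trials = simulate_trials(TrialConfig(seed=5))
        res = fit_accuracy_model(trials)
        assert res.coef("cue_number") == pytest.approx(-0.00780678, abs=1e-6)
        assert res.se("cue_number") == pytest.approx(0.00129294, abs=1e-6)
        assert res.coef("intercept") == pytest.approx(1.00219780, abs=1e-6)
        assert res.variance_components["participant_slope"] == pytest.approx(1.28635e-05, abs=1e-8)
        assert res.residual_var == pytest.approx(1.28522e-03, abs=1e-7)

    def test_all_correct_gives_zero_slope(self):
        trials = simulate_trials(TrialConfig(
            accuracy_intercept=1.0, accuracy_slope=0.0,
            participant_intercept_sd=0.0, participant_slope_sd=0.0, seed=1))
        res = fit_accuracy_model(trials)
        assert res.coef("cue_number") == pytest.approx(0.0, abs=1e-12)

    def test_generate_then_refit_recovers_slope(self):
        cfg = TrialConfig(accuracy_slope=-0.02, accuracy_intercept=0.95,
                          n_participants=26, trials_per_participant=400, seed=8)
        res = fit_accuracy_model(simulate_trials(cfg))
        lo, hi = res.conf_int("cue_number")
        assert lo < -0.02 < hi

    def test_single_cue_participant_dropped_with_warning(self):
        trials = simulate_trials(TrialConfig(n_participants=5, seed=2))
        extra = pd.DataFrame({"participant_id": ["lone"] * 10,
                              "cue_number": [3] * 10,
                              "correct": [True] * 10})
        res = fit_accuracy_model(pd.concat([trials, extra], ignore_index=True))
        assert res.n_individuals == 5
        assert any("lone" in w for w in res.warnings)
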