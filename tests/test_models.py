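"""Association models: logistic OR, age-timescale Cox HR, suite layout."""

import numpy as np
import pandas as pd
import pytest

import certscore as cs
from certscore import models
from certscore.errors import (
    ConfigurationError,
    DataError,
    DegeneratePredictorError,
)
from conftest import single_effect_config


def make_survival_frame(entry, exit_, event, x, sex=None):
    n = len(entry)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "sex": sex if sex is not None else ["male"] * n,
            "age_baseline": np.asarray(entry, dtype=float),
            "age_at_event_or_censor": np.asarray(exit_, dtype=float),
            "event_new_onset": np.asarray(event, dtype=bool),
            "prevalent_htn": [False] * n,
            "x": np.asarray(x, dtype=float),
        }
    )


def cox_partial_loglik(beta, entry, exit_, event, x):
    """Brute-force left-truncated Cox partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(x)):
        if not event[i]:
            continue
        t = exit_[i]
        risk = [j for j in range(len(x)) if entry[j] < t <= exit_[j]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestClassifyPrevalent:
    @pytest.mark.parametrize(
        "sbp, dbp, tx, expected",
        [
            (150, 85, False, True),    # SBP threshold
            (120, 70, True, True),     # treatment alone
            (139, 89, False, False),   # just below both
            (139, 90, False, True),    # DBP threshold inclusive
            (140, 70, False, True),    # SBP threshold inclusive
        ],
    )
    def test_threshold_rule(self, sbp, dbp, tx, expected):
        assert cs.classify_prevalent(sbp, dbp, tx) is expected

    def test_vectorised(self):
        out = cs.classify_prevalent([150, 120], [85, 70], [False, False])
        assert out.tolist() == [True, False]


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = cs.standardize_predictor([1.0, 2.0, 3.0])
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        z = cs.standardize_predictor(rng.normal(size=50))
        np.testing.assert_allclose(cs.standardize_predictor(z), z, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, size=80)
        np.testing.assert_allclose(
            cs.standardize_predictor(3.5 * x - 11.0),
            cs.standardize_predictor(x),
            atol=1e-10,
        )

    def test_constant_input_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            cs.standardize_predictor([2.0] * 10)


class TestLogistic:
    def test_binary_predictor_equals_cross_product_ratio(self):
        # exposed: 20/100 events; unexposed: 10/100 -> OR = (20*90)/(80*10)
        y = [1] * 20 + [0] * 80 + [1] * 10 + [0] * 90
        x = [1] * 100 + [0] * 100
        df = pd.DataFrame({"prevalent_htn": [bool(v) for v in y], "x": x,
                           "sex": "female"})
        r = cs.fit_prevalent(df, "x", "unadjusted")
        assert r.effect_type == "OR"
        assert r.estimate == pytest.approx(2.25, rel=1e-6)
        assert r.ci_low < 2.25 < r.ci_high
        assert r.n_used == 200

    def test_generator_fit_round_trip(self):
        cfg = single_effect_config(20000, seed=77, beta_or=0.35)
        coh = cs.simulate_cohort(cfg)
        df = models.prepare_predictors(coh, ["cert2"])
        r = cs.fit_prevalent(df, "cert2", "unadjusted")
        assert r.ci_low < np.exp(0.35) < r.ci_high

    def test_null_predictor_covers_one(self):
        cfg = single_effect_config(20000, seed=5)
        coh = cs.simulate_cohort(cfg)
        rng = np.random.default_rng(6)
        coh = coh.assign(noise=rng.normal(size=len(coh)))
        r = cs.fit_prevalent(coh, "noise", "unadjusted")
        assert r.ci_low < 1.0 < r.ci_high

    def test_separation_reported(self):
        df = pd.DataFrame(
            {"prevalent_htn": [True] * 10 + [False] * 10,
             "x": [1.0] * 10 + [0.0] * 10, "sex": "male"}
        )
        with pytest.raises(cs.errors.ConvergenceError):
            cs.fit_prevalent(df, "x", "unadjusted")

    def test_exclusion_bookkeeping(self, small_cohort):
        df = models.prepare_predictors(small_cohort, ["cert2"])
        df.loc[df.index[:7], "tc"] = np.nan
        r = cs.fit_prevalent(df, "cert2", "M2")
        assert r.n_used + r.n_excluded == len(df)
        assert r.n_excluded == 7


class TestCox:
    def test_matches_grid_search_partial_likelihood(self):
        # the event subject's covariate is interior to the risk set's range,
        # so the partial-likelihood maximum is finite
        entry = [50.0, 51.0, 52.0]
        exit_ = [55.0, 56.0, 57.0]
        event = [True, False, False]
        x = [0.2, 1.4, -0.7]
        df = make_survival_frame(entry, exit_, event, x)
        r = cs.fit_new_onset(df, "x", "unadjusted")
        grid = np.linspace(-4, 4, 8001)
        ll = [cox_partial_loglik(b, entry, exit_, event, x) for b in grid]
        beta_star = grid[int(np.argmax(ll))]
        assert np.log(r.estimate) == pytest.approx(beta_star, abs=1e-3)

    def test_five_subject_oracle_with_truncation(self):
        entry = [40.0, 45.0, 47.0, 50.0, 52.0]
        exit_ = [49.0, 53.0, 55.0, 58.0, 60.0]
        event = [True, False, True, False, True]
        x = [1.0, 0.0, -1.0, 0.5, 2.0]
        df = make_survival_frame(entry, exit_, event, x)
        r = cs.fit_new_onset(df, "x", "unadjusted")
        grid = np.linspace(-4, 4, 8001)
        ll = [cox_partial_loglik(b, entry, exit_, event, x) for b in grid]
        assert np.log(r.estimate) == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_two_group_hazard_ratio_recovery(self):
        # exponential onset on the age axis with true HR 2.0
        rng = np.random.default_rng(8)
        n = 20000
        grp = (np.arange(n) % 2).astype(float)
        lam = 0.03 * np.exp(np.log(2.0) * grp)
        entry = np.full(n, 50.0)
        t = entry + rng.exponential(1.0 / lam)
        cens = entry + 10.0
        event = t <= cens
        exit_ = np.minimum(t, cens)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        df = make_survival_frame(entry, exit_, event, grp, sex=sex)
        r = cs.fit_new_onset(df, "x", "unadjusted")
        assert 1.9 <= r.estimate <= 2.1

    def test_m1_is_not_fitted(self, small_cohort):
        df = models.prepare_predictors(small_cohort, ["cert2"])
        with pytest.raises(ConfigurationError, match="timescale"):
            cs.fit_new_onset(df, "cert2", "M1")

    def test_exit_before_entry_is_data_error(self):
        df = make_survival_frame([50.0, 51.0, 52.0, 53.0],
                                 [55.0, 51.0, 57.0, 58.0],
                                 [True, False, True, False],
                                 [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(DataError, match="P1"):
            cs.fit_new_onset(df, "x", "unadjusted")

    def test_zero_events_in_stratum_named(self):
        df = make_survival_frame([50.0] * 6, [55.0] * 6,
                                 [True, True, True, False, False, False],
                                 [0.1, 0.5, 0.9, 0.2, 0.6, 1.0],
                                 sex=["male"] * 3 + ["female"] * 3)
        with pytest.raises(DataError, match="female"):
            cs.fit_new_onset(df, "x", "unadjusted")


class TestSuite:
    def test_cert_rows_match_wide_table_layout(self, small_cohort):
        res = cs.run_association_suite(small_cohort, predictors=["cert1", "cert2"])
        # 2 scores x (1 unadjusted + 3 adjusted) logistic + 2 x 3 Cox (M1 skipped)
        assert len(res) == 14
        wide = cs.format_cert_table(res)
        assert len(wide) == 8
        m1 = wide[wide["model"] == "M1"]
        assert (m1["HR (95% CI)"] == "-").all()
        assert (m1["OR (95% CI)"] != "-").all()

    def test_lipid_predictor_count(self, small_cohort):
        res = cs.run_association_suite(
            small_cohort,
            predictors=models.LIPID_PREDICTORS,
            outcomes=("prevalent",),
        )
        assert len(res) == 13 * 4
        assert set(res["effect_type"]) == {"OR"}

    def test_empty_predictor_list(self, small_cohort):
        res = cs.run_association_suite(small_cohort, predictors=[])
        assert len(res) == 0

    def test_unknown_predictor_lists_valid_names(self, small_cohort):
        with pytest.raises(ConfigurationError, match="cert1"):
            cs.run_association_suite(small_cohort, predictors=["cer_99_9"])

    def test_score_shift_leaves_effect_unchanged(self, small_cohort):
        df = models.prepare_predictors(small_cohort, ["cert2"])
        r1 = cs.fit_prevalent(df, "cert2", "unadjusted")
        df2 = df.assign(cert2=df["cert2"] + 5)
        r2 = cs.fit_prevalent(df2, "cert2", "unadjusted")
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-8)

    def test_sex_stratified_and_interaction(self, small_cohort):
        res = cs.run_association_suite(
            small_cohort, predictors=["cert2"], outcomes=("prevalent",),
            models=("unadjusted",), sex_stratified=True,
        )
        assert set(res["model"]) == {"unadjusted", "unadjusted:male", "unadjusted:female"}
        df = models.prepare_predictors(small_cohort, ["cert2"])
        p = models.fit_sex_interaction(df, "cert2", "prevalent", "unadjusted")
        assert 0.0 <= p <= 1.0
        p2 = models.fit_sex_interaction(df, "cert2", "new_onset", "unadjusted")
        assert 0.0 <= p2 <= 1.0
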