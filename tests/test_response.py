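"""Endpoint and subgroup models: closed-form oracles, null calibration and
classification rules."""

import numpy as np
import pandas as pd
import pytest

from bsetrial import response
from bsetrial.datamodel import DomainError, TrialDataset
from conftest import make_trial_frame


def _dataset(**kw):
    return TrialDataset(table=make_trial_frame(**kw))


class TestPrimaryModel:
    def test_noise_free_effect(self):
        df = make_trial_frame(20, 20, seed=1)
        base = df["baseline_glucose"]
        df["week12_glucose"] = base - np.where(df.arm == "BSE", 0.5, 0.0)
        est = response.primary_endpoint_model(TrialDataset(table=df))
        assert est.estimate == pytest.approx(-0.5, abs=1e-10)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_sign_convention(self):
        # positive improvement in BSE arm => negative treatment coefficient
        ds = _dataset(n_bse=5000, n_pla=5000, effect=0.3, seed=2)
        est = response.primary_endpoint_model(ds)
        assert est.estimate < 0

    def test_single_arm_rejected(self):
        df = make_trial_frame(10, 10)
        df["arm"] = "BSE"
        with pytest.raises(DomainError):
            response.primary_endpoint_model(TrialDataset(table=df))

    def test_type_i_error_nominal(self):
        """Under a matched null (no effect) the primary model rejects at the
        nominal 5% rate (2000 replicates, +-2 MC SEs)."""
        rejections = 0
        reps = 2000
        for s in range(reps):
            ds = _dataset(n_bse=30, n_pla=30, effect=0.0, seed=10_000 + s)
            rejections += response.primary_endpoint_model(ds).p_value < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate == pytest.approx(0.05, abs=2 * se + 1e-12)


class TestAncova:
    def test_noise_free_effect(self):
        df = make_trial_frame(15, 15, seed=3)
        df["week12_glucose"] = df["baseline_glucose"] - \
            np.where(df.arm == "BSE", 0.5, 0.0)
        est = response.ancova_model(TrialDataset(table=df))
        assert est.estimate == pytest.approx(-0.5, abs=1e-10)

    def test_equals_change_score_when_baseline_coef_forced_to_one(self):
        """Algebraic identity: regressing (week12 - baseline) on treatment is
        the ANCOVA model with the baseline coefficient pinned at 1."""
        import statsmodels.formula.api as smf
        df = make_trial_frame(40, 40, effect=0.25, seed=4)
        df["treat"] = (df.arm == "BSE").astype(int)
        df["d_glucose"] = df.week12_glucose - df.baseline_glucose
        change = smf.ols("d_glucose ~ treat", data=df).fit()
        # offset formulation pins the baseline coefficient at exactly 1
        pinned = smf.ols("I(week12_glucose - baseline_glucose) ~ treat",
                         data=df).fit()
        assert change.params["treat"] == pytest.approx(
            pinned.params["treat"], abs=1e-12)

    def test_type_i_error_nominal(self):
        rejections = 0
        reps = 2000
        for s in range(reps):
            ds = _dataset(n_bse=30, n_pla=30, effect=0.0, seed=30_000 + s)
            rejections += response.ancova_model(ds).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps == pytest.approx(0.05, abs=2 * se)


def _clustered_frame(n_per_cell=50, effects=(0.4, 0.0), seed=0, sd=0.63):
    """Two clusters x two arms with cluster-specific BSE effects."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for ci, (clu, eff) in enumerate(zip(("MARD-like", "MOD-like"), effects)):
        for arm in ("BSE", "placebo"):
            for _ in range(n_per_cell):
                base = rng.normal(6.4, 0.2)
                imp = (eff if arm == "BSE" else 0.0) + rng.normal(0, sd)
                rows.append({
                    "participant_id": f"P{pid:05d}", "arm": arm,
                    "completed": True, "baseline_glucose": base,
                    "week12_glucose": base - imp,
                    "baseline_bmi": rng.normal(32, 3),
                    "baseline_insulin": 19.0, "week12_insulin": 19.0,
                    "cluster": clu,
                })
                pid += 1
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_cell_mean_algebra(self):
        """Two-group noise-free toy: contrasts equal the cell-mean
        differences exactly."""
        df = _clustered_frame(n_per_cell=10, effects=(0.4, 0.1), seed=5, sd=0)
        labels = df.pop("cluster")
        res = response.interaction_model(TrialDataset(table=df), labels)
        assert res["contrasts"]["MARD-like"].estimate == pytest.approx(-0.4, abs=1e-10)
        assert res["contrasts"]["MOD-like"].estimate == pytest.approx(-0.1, abs=1e-10)

    def test_mard_effect_recovery(self):
        df = _clustered_frame(n_per_cell=5000, effects=(0.4, 0.0), seed=6)
        labels = df.pop("cluster")
        res = response.interaction_model(TrialDataset(table=df), labels)
        se = 0.63 * np.sqrt(2 / 5000)
        assert res["contrasts"]["MARD-like"].estimate == pytest.approx(-0.4, abs=4 * se)
        assert res["interaction_p"] < 1e-6

    def test_interaction_p_uniform_under_null(self):
        from scipy.stats import kstest
        ps = []
        for s in range(400):
            df = _clustered_frame(n_per_cell=20, effects=(0.2, 0.2),
                                  seed=50_000 + s)
            labels = df.pop("cluster")
            ps.append(response.interaction_model(
                TrialDataset(table=df), labels)["interaction_p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_arm_group_dropped(self):
        df = _clustered_frame(n_per_cell=10, seed=7)
        labels = df.pop("cluster")
        solo = df.sample(1, random_state=0).index
        labels = labels.copy()
        labels.loc[solo] = "SIDD-like"
        with pytest.warns(UserWarning, match="one arm"):
            res = response.interaction_model(TrialDataset(table=df), labels)
        assert "SIDD-like" not in res["contrasts"]


class TestClassification:
    def test_fixed_threshold_rule(self):
        # exact binary fractions so the inclusive >= comparison is exact
        df = make_trial_frame(4, 1, seed=8)
        df["baseline_glucose"] = 6.5
        df["week12_glucose"] = 6.5 - np.array([0.5, 0.25, 0.125, 0.0, 0.125])
        labels = response.classify_responders(TrialDataset(table=df),
                                              threshold=0.25)
        assert labels["pronounced_responder"].sum() == 2  # 0.5 and 0.25 inclusive

    def test_quantile_mode_all_equal(self):
        df = make_trial_frame(4, 1, seed=9)
        df["week12_glucose"] = df["baseline_glucose"] - 0.25
        labels = response.classify_responders(TrialDataset(table=df),
                                              mode="quantile")
        # threshold equals the common improvement; inclusive rule labels all
        assert labels["pronounced_responder"].all()

    def test_quantile_matches_brute_force(self):
        ds = _dataset(n_bse=35, n_pla=35, effect=0.15, seed=10)
        labels = response.classify_responders(ds, mode="quantile")
        imp = labels["improvement"].to_numpy()
        thr = np.percentile(imp, 75)
        np.testing.assert_array_equal(labels["pronounced_responder"],
                                      imp >= thr)

    def test_remission_strict_threshold(self):
        df = make_trial_frame(3, 1, seed=11)
        df["baseline_glucose"] = 6.5
        df.loc[df.index[:3], "week12_glucose"] = [6.0, 6.1, 6.0999]
        out = response.classify_remission(TrialDataset(table=df))
        assert out["remission"].tolist()[:3] == [True, False, True]

    def test_vectorized_equals_elementwise(self):
        ds = _dataset(n_bse=50, n_pla=10, effect=0.2, seed=12)
        out = response.classify_remission(ds)
        manual = [g < 6.1 for g in out["week12_glucose"]]
        assert out["remission"].tolist() == manual


class TestBt2160Interaction:
    def test_null_interaction_p_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(400):
            n = 40
            is_mard = rng.random(n) < 0.6
            bt = np.exp(rng.normal(np.log(0.027), 0.5, n))
            d_glu = rng.normal(0, 0.63, n)
            bsa = rng.normal(1.9, 0.2, n)
            res = response.bt2160_cluster_interaction(d_glu, bt, is_mard, bsa)
            ps.append(res["interaction"].p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_mard_only_dependence_detected(self):
        rng = np.random.default_rng(14)
        n = 4000
        is_mard = rng.random(n) < 0.6
        log_bt = rng.normal(np.log(0.027), 0.5, n)
        noise = rng.normal(0, 0.4, n)
        # steeper (more negative) slope of d_glucose on log BT within MARD
        d_glu = np.where(is_mard, -0.5 * log_bt, 0.0) + noise
        res = response.bt2160_cluster_interaction(
            d_glu, np.exp(log_bt), is_mard, rng.normal(1.9, 0.2, n))
        assert res["interaction"].estimate == pytest.approx(-0.5, abs=0.1)
        assert res["interaction"].p_value < 1e-6

    def test_zero_abundance_pseudocount(self):
        x = np.array([0.0, 0.1, 0.2, 0.4])
        logged = response.log_abundance(x)
        assert logged[0] == pytest.approx(np.log(0.05))


class TestStratifiedByMedian:
    def test_null_contrasts_near_zero(self):
        rng = np.random.default_rng(15)
        n = 6000
        res = response.stratified_by_median(
            rng.normal(0.1, 0.63, n),
            np.exp(rng.normal(np.log(0.027), 0.5, n)),
            rng.random(n) < 0.6)
        for eff in res["contrasts"].values():
            assert abs(eff.estimate) < 4 * 0.63 * np.sqrt(2 / (n / 4))

    def test_median_split_matches_sort_oracle(self):
        rng = np.random.default_rng(16)
        n = 101  # odd: the median element itself goes to the lower stratum
        bt = rng.random(n)
        imp = rng.normal(0, 1, n)
        is_mard = rng.random(n) < 0.5
        res = response.stratified_by_median(imp, bt, is_mard)
        med = np.sort(bt)[n // 2]
        assert res["median"] == pytest.approx(med)
        n_above = int((bt > med).sum())
        assert res["contrasts"]["above"].n_used + \
            res["contrasts"]["below"].n_used == n
        # ties (the median itself) fall in the lower stratum
        assert n_above == res["contrasts"]["above"].n_used


class TestRemissionModel:
    def test_r2_equals_squared_correlation_identity(self):
        rng = np.random.default_rng(17)
        n = 200
        bt = np.exp(rng.normal(np.log(0.03), 0.5, n))
        ggt = rng.normal(0.7, 0.3, n).clip(0.1)
        y = ((np.log(bt) - ggt + rng.normal(0, 0.8, n)) > np.log(0.03) - 0.7)
        res = response.remission_model(y, bt, ggt)
        # linear-model identity: R^2 = corr(fitted, observed)^2
        import statsmodels.formula.api as smf
        df = pd.DataFrame({"remission": y.astype(float),
                           "log_bt": np.log(bt), "ggt": ggt})
        fit = smf.ols("remission ~ log_bt + ggt", data=df).fit()
        assert res["r_squared"] == pytest.approx(
            np.corrcoef(fit.fittedvalues, df.remission)[0, 1] ** 2, abs=1e-10)

    def test_independent_covariates_r2_near_zero(self):
        rng = np.random.default_rng(18)
        n = 20_000
        y = rng.random(n) < 0.3
        res = response.remission_model(
            y, np.exp(rng.normal(-3.5, 0.5, n)), rng.normal(0.7, 0.3, n))
        assert res["r_squared"] < 4 * 2 / n + 0.002

    def test_constant_outcome_rejected(self):
        with pytest.raises(DomainError):
            response.remission_model(np.ones(10), np.ones(10) * 0.03,
                                     np.ones(10) * 0.7)

    def test_logistic_alternative(self):
        rng = np.random.default_rng(19)
        n = 300
        bt = np.exp(rng.normal(np.log(0.03), 0.5, n))
        y = rng.random(n) < 1 / (1 + np.exp(-(np.log(bt) + 3.5) * 3))
        res = response.remission_model(y, bt, rng.normal(0.7, 0.2, n).clip(0.1),
                                       family="logistic")
        assert 0 <= res["r_squared"] <= 1
        assert res["p_values"]["log_bt"] < 0.01


def test_improvement_and_model_change_are_negatives(small_trial):
    frame = response._analysis_frame(small_trial)
    np.testing.assert_allclose(frame["improvement"], -frame["d_glucose"])
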