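"""3-year relapse-free logistic model, ROC/Youden and AUC comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from neoquant.riskmodel import (
    RelapseRiskModel,
    auc_pair_counting,
    compare_auc,
    eligible_at_horizon,
    predict_probability,
    relapse_free_outcome,
    roc_analysis,
)


def make_clinical(ttr_time, ttr_event, rng=None, index=None):
    n = len(ttr_time)
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "ttr_time": ttr_time,
            "ttr_event": ttr_event,
            "rfs_time": ttr_time,
            "rfs_event": ttr_event,
            "sex": rng.choice(["M", "F"], n),
            "stage": rng.choice(["I", "II", "III"], n),
            "smoking": rng.integers(0, 2, n),
            "histology": rng.choice(["ADC", "SCC"], n),
            "egfr": 0,
            "kras": 0,
        },
        index=index if index is not None else pd.RangeIndex(n),
    )


class TestEligibility:
    def test_censored_before_horizon_excluded(self):
        clin = make_clinical([30.0, 40.0, 20.0], [0, 0, 1])
        elig = eligible_at_horizon(clin, 36.0)
        assert list(elig) == [False, True, True]

    def test_outcome_coding(self):
        clin = make_clinical([20.0, 40.0, 50.0], [1, 0, 1])
        out = relapse_free_outcome(clin, 36.0)
        assert out.iloc[0] == 0.0  # relapsed before horizon
        assert out.iloc[1] == 1.0  # followed event-free past horizon
        assert out.iloc[2] == 1.0  # relapsed after horizon, still RF at 3y

    def test_eligible_count_identity(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 80, 200)
        e = rng.random(200) < 0.5
        clin = make_clinical(t, e.astype(int), rng)
        elig = eligible_at_horizon(clin, 36.0)
        n_event_before = int(((t <= 36.0) & e).sum())
        n_followed = int((t >= 36.0).sum())
        assert int(elig.sum()) == n_event_before + n_followed


class TestPredictProbability:
    def test_arithmetic(self):
        p = predict_probability({"const": 0.0, "x": np.log(2)}, {"x": 1.0})
        assert p == pytest.approx(2 / 3)

    def test_zero_coefficients_give_half(self):
        assert predict_probability({"const": 0.0, "x": 0.0}, {"x": 3.0}) == 0.5

    def test_mirror_symmetry(self):
        params = {"const": 0.3, "x": 1.7}
        mirror = {"const": -0.3, "x": -1.7}
        x = {"x": 0.9}
        assert predict_probability(params, x) + \
            predict_probability(mirror, x) == pytest.approx(1.0)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            predict_probability({"const": 0.0, "x": 1.0}, {})


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = np.round(rng.normal(size=50), 1)  # ties included
            labels = (rng.random(50) < 0.5).astype(int)
            if labels.sum() in (0, 50):
                continue
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_label_inversion_maps_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])

    def test_dichotomise_uses_youden_cutoff(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        groups = roc.dichotomise()
        assert list(groups) == ["high", "high", "low", "low"]


class TestCompareAUC:
    def test_identical_rocs_give_p_one(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        roc = roc_analysis(scores, labels)
        z, p = compare_auc(roc, roc)
        assert p == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            labels = np.r_[np.ones(50, int), np.zeros(50, int)]
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            _, p = compare_auc(roc_analysis(a, labels), roc_analysis(b, labels))
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_power_against_perfect_vs_random(self):
        rng = np.random.default_rng(6)
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        perfect = np.r_[np.ones(50), np.zeros(50)]
        noise = rng.normal(size=100)
        _, p = compare_auc(roc_analysis(perfect, labels),
                           roc_analysis(noise, labels))
        assert p < 0.01

    def test_mismatched_subjects_rejected(self):
        labels = np.array([1, 1, 0, 0])
        r1 = roc_analysis([0.9, 0.8, 0.2, 0.1], labels)
        r2 = roc_analysis([0.9, 0.8, 0.2, 0.1], 1 - labels)
        with pytest.raises(ValueError):
            compare_auc(r1, r2)


def simulate_logistic_cohort(n, beta, seed, prevalence_intercept=0.0):
    """Patients whose 3-year relapse status follows a logistic law on a
    log-transformed feature."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(np.log(500), 1.2, n)
    eta = prevalence_intercept + beta * np.log1p(x)
    eta -= beta * np.mean(np.log1p(x))  # centre so prevalence ~ intercept
    y = rng.random(n) < expit(eta)
    # outcome=1 -> event-free past horizon; outcome=0 -> relapse before
    ttr_time = np.where(y, 60.0, 12.0)
    ttr_event = np.where(y, 0, 1)
    features = pd.DataFrame({"neoantigen_load": x},
                            index=pd.RangeIndex(n))
    clinical = make_clinical(ttr_time, ttr_event, rng,
                             index=pd.RangeIndex(n))
    return features, clinical


class TestRelapseModel:
    def test_known_coefficient_recovered_at_n500(self):
        features, clinical = simulate_logistic_cohort(500, beta=1.0, seed=7)
        model = RelapseRiskModel(features, clinical, ["neoantigen_load"],
                                 adjust=())
        res = model.fit()
        assert res.params["log_neoantigen_load"] == pytest.approx(1.0, abs=0.2)

    def test_null_simulation_slopes_near_zero(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            features, clinical = simulate_logistic_cohort(200, beta=0.0,
                                                          seed=seed)
            res = RelapseRiskModel(features, clinical, ["neoantigen_load"],
                                   adjust=()).fit()
            slope = res.params["log_neoantigen_load"]
            se = res.bse["log_neoantigen_load"]
            hits += abs(slope) < 3 * se
        assert hits >= reps - 2

    def test_censored_patient_excluded_from_model(self):
        features, clinical = simulate_logistic_cohort(50, beta=0.5, seed=8)
        clinical.iloc[0, clinical.columns.get_loc("ttr_time")] = 30.0
        clinical.iloc[0, clinical.columns.get_loc("ttr_event")] = 0
        model = RelapseRiskModel(features, clinical, ["neoantigen_load"])
        assert model.n == 49

    def test_noise_feature_barely_moves_training_auc(self):
        features, clinical = simulate_logistic_cohort(500, beta=1.0, seed=9)
        rng = np.random.default_rng(10)
        features["noise"] = rng.lognormal(0.0, 1.0, size=len(features))
        base = RelapseRiskModel(features, clinical, ["neoantigen_load"],
                                adjust=())
        res_b = base.fit()
        auc_b = roc_analysis(
            res_b.predict_probability(base.transformed_design()),
            base.outcome.to_numpy(),
        ).auc
        both = RelapseRiskModel(features, clinical,
                                ["neoantigen_load", "noise"], adjust=())
        res_2 = both.fit()
        auc_2 = roc_analysis(
            res_2.predict_probability(both.transformed_design()),
            both.outcome.to_numpy(),
        ).auc
        assert abs(auc_2 - auc_b) < 0.05
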