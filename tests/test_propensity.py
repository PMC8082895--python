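import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from colocea.propensity import (
    DegenerateDataError,
    OUTCOME_COVARIATES,
    PropensityModel,
    SeparationError,
    StudyRecord,
    TREATMENT_COVARIATES,
    balance_check,
    fit_logistic,
    match,
    score,
)
from colocea.synth import SyntheticStudySpec, generate_study


def null_study(n, seed):
    return generate_study(
        SyntheticStudySpec(
            n=n,
            coefficients={"intercept": 0.0, "age": 0.0, "sex": 0.0,
                          "device_used": 0.0, "cecal_intubation": 0.0},
            seed=seed,
        )
    )


class TestFitLogistic:
    def test_null_model_recovery_within_3_se(self):
        records = null_study(5000, seed=10)
        model = fit_logistic(records, OUTCOME_COVARIATES)
        for term in ("(intercept)",) + OUTCOME_COVARIATES:
            est = model.intercept if term == "(intercept)" else model.coefficients[term]
            assert abs(est) < 3 * model.standard_errors[term]

    def test_generating_coefficients_recovered(self):
        spec = SyntheticStudySpec(
            n=5000,
            coefficients={"intercept": -3.5, "age": 0.05, "sex": 0.8,
                          "device_used": 0.5, "cecal_intubation": 1.0},
            seed=42,
        )
        model = fit_logistic(generate_study(spec), OUTCOME_COVARIATES)
        for name, truth in [("age", 0.05), ("sex", 0.8), ("device_used", 0.5)]:
            assert abs(model.coefficients[name] - truth) < 3 * model.standard_errors[name]

    def test_log_likelihood_dominates_null(self):
        records = generate_study(SyntheticStudySpec(n=800, seed=3))
        full = fit_logistic(records, OUTCOME_COVARIATES)
        y = np.array([r.success for r in records])
        pbar = y.mean()
        ll_null = float(np.sum(y * np.log(pbar) + (1 - y) * np.log1p(-pbar)))
        assert full.log_likelihood >= ll_null

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        records = generate_study(SyntheticStudySpec(n=400, seed=8))
        model = fit_logistic(records, TREATMENT_COVARIATES, outcome="device_used")
        X = np.column_stack([
            np.ones(len(records)),
            [r.age for r in records],
            [r.sex for r in records],
        ])
        y = np.array([r.device_used for r in records])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fitted = np.array([model.intercept, model.coefficients["age"], model.coefficients["sex"]])
        assert np.allclose(fitted, ref.params, atol=1e-6)

    def test_constant_outcome_rejected(self):
        records = [
            StudyRecord(age=60 + i, sex=i % 2, device_used=i % 2, cecal_intubation=0.9, success=1)
            for i in range(30)
        ]
        with pytest.raises(DegenerateDataError):
            fit_logistic(records, TREATMENT_COVARIATES)

    def test_complete_separation_detected(self):
        records = [
            StudyRecord(age=40.0 + i, sex=0, device_used=0, cecal_intubation=0.5,
                        success=int(i >= 15))
            for i in range(30)
        ]
        with pytest.raises(SeparationError):
            fit_logistic(records, ("age",))

    def test_too_few_records_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_logistic(null_study(5, seed=0), TREATMENT_COVARIATES)


class TestScore:
    def make_model(self, intercept, coeffs):
        return PropensityModel(
            covariate_names=tuple(coeffs),
            intercept=intercept,
            coefficients=coeffs,
            converged=True,
            n_iter=1,
            log_likelihood=0.0,
        )

    def test_null_model_scores_half(self):
        model = self.make_model(0.0, {"age": 0.0, "sex": 0.0})
        recs = null_study(20, seed=1)
        assert np.allclose(score(model, recs), 0.5)

    def test_intercept_log3_scores_three_quarters(self):
        model = self.make_model(np.log(3.0), {"age": 0.0, "sex": 0.0})
        assert np.allclose(score(model, null_study(10, seed=2)), 0.75)

    def test_monotone_in_positive_coefficient(self):
        model = self.make_model(0.0, {"age": 0.1, "sex": 0.0})
        recs = [StudyRecord(age=a, sex=0, device_used=0, cecal_intubation=0.5, success=0)
                for a in (50.0, 60.0, 70.0)]
        s = score(model, recs)
        assert s[0] < s[1] < s[2]

    def test_permutation_equivariance(self):
        records = null_study(50, seed=6)
        model = fit_logistic(records, TREATMENT_COVARIATES, outcome="device_used")
        s = score(model, records)
        perm = np.random.default_rng(0).permutation(len(records))
        s_perm = score(model, [records[i] for i in perm])
        assert np.allclose(s_perm, s[perm])

    def test_unconverged_model_rejected(self):
        model = self.make_model(0.0, {"age": 0.0, "sex": 0.0})
        model.converged = False
        with pytest.raises(ValueError):
            score(model, null_study(10, seed=2))


class TestMatch:
    def test_identical_lists_pair_perfectly(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        m = match(scores, scores, caliper=0.01)
        assert len(m.pairs) == 4
        assert m.unmatched_treated == 0
        for t, c in m.pairs:
            assert scores[t] == scores[c]

    def test_nearest_control_within_caliper_chosen(self):
        # treated at logit 0; controls at logits 0.1 and 5; caliper 0.2
        inv = lambda x: 1.0 / (1.0 + np.exp(-x))
        m = match([inv(0.0)], [inv(0.1), inv(5.0)], caliper=0.2)
        assert m.pairs == ((0, 1 - 1),)  # pairs with the 0.1-logit control

    def test_caliper_never_exceeded(self):
        rng = np.random.default_rng(13)
        st, sc = rng.uniform(0.05, 0.95, 40), rng.uniform(0.05, 0.95, 50)
        m = match(st, sc, caliper=0.1)
        lt = np.log(st / (1 - st))
        lc = np.log(sc / (1 - sc))
        for t, c in m.pairs:
            assert abs(lt[t] - lc[c]) <= 0.1 + 1e-12
        assert len(m.pairs) + m.unmatched_treated == len(st)

    def test_controls_used_at_most_once(self):
        rng = np.random.default_rng(14)
        m = match(rng.uniform(0.2, 0.8, 30), rng.uniform(0.2, 0.8, 20), caliper=5.0)
        controls = [c for _, c in m.pairs]
        assert len(controls) == len(set(controls))
        assert len(m.pairs) <= 20

    def test_greedy_against_optimal_assignment_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            nt, nc = rng.integers(2, 8), rng.integers(2, 8)
            st = rng.uniform(0.1, 0.9, nt)
            sc = rng.uniform(0.1, 0.9, nc)
            m = match(st, sc, caliper=50.0)  # caliper effectively off
            lt = np.log(st / (1 - st))
            lc = np.log(sc / (1 - sc))
            greedy_total = sum(abs(lt[t] - lc[c]) for t, c in m.pairs)
            cost = np.abs(lt[:, None] - lc[None, :])
            rows, cols = linear_sum_assignment(cost)
            optimal_total = cost[rows, cols].sum()
            assert greedy_total >= optimal_total - 1e-9

    def test_greedy_equals_oracle_on_non_overlapping_clusters(self):
        # well-separated score clusters: greedy must find the optimum
        st = [0.2, 0.5, 0.8]
        sc = [0.21, 0.51, 0.81]
        m = match(st, sc, caliper=1.0)
        lt = np.log(np.array(st) / (1 - np.array(st)))
        lc = np.log(np.array(sc) / (1 - np.array(sc)))
        cost = np.abs(lt[:, None] - lc[None, :])
        rows, cols = linear_sum_assignment(cost)
        assert sum(cost[t, c] for t, c in m.pairs) == pytest.approx(cost[rows, cols].sum())

    def test_nonpositive_caliper_rejected(self):
        with pytest.raises(ValueError):
            match([0.5], [0.5], caliper=0.0)


class TestBalance:
    def imbalanced_study(self, n=4000, seed=20):
        # device use strongly age-dependent: older patients treated more
        rng = np.random.default_rng(seed)
        records = []
        for _ in range(n):
            age = rng.normal(60, 8)
            p_dev = 1.0 / (1.0 + np.exp(-(age - 60) * 0.15))
            dev = int(rng.random() < p_dev)
            records.append(
                StudyRecord(age=float(age), sex=int(rng.random() < 0.54), device_used=dev,
                            cecal_intubation=float(rng.beta(8, 1.5)), success=int(rng.random() < 0.8))
            )
        return records

    def test_identical_groups_zero_smd(self):
        recs = [StudyRecord(age=60.0 + i, sex=i % 2, device_used=0, cecal_intubation=0.9, success=1)
                for i in range(10)]
        m = match([0.5] * 10, [0.5] * 10, caliper=0.1)
        smd = balance_check(recs, recs, m)
        assert (smd["smd"] == 0).all()

    def test_matching_reduces_age_imbalance(self):
        records = self.imbalanced_study()
        model = fit_logistic(records, TREATMENT_COVARIATES, outcome="device_used")
        scores = score(model, records)
        treated = [r for r in records if r.device_used == 1]
        control = [r for r in records if r.device_used == 0]
        st = scores[[r.device_used == 1 for r in records]]
        sc = scores[[r.device_used == 0 for r in records]]

        # pre-matching SMD via a trivial full pairing of equal-length heads
        k = min(len(treated), len(control))
        pre = balance_check(treated[:k], control[:k],
                            match([0.5] * k, [0.5] * k, caliper=1.0))
        post = balance_check(treated, control, match(st, sc))
        smd_pre = abs(pre.loc[pre.covariate.eq("age"), "smd"].iloc[0])
        smd_post = abs(post.loc[post.covariate.eq("age"), "smd"].iloc[0])
        assert smd_pre > 0.5  # the generator induces a strong imbalance
        assert smd_post < 0.5 * smd_pre

    def test_single_identical_pair_degenerate_flag(self):
        rec = StudyRecord(age=60.0, sex=1, device_used=1, cecal_intubation=0.9, success=1)
        m = match([0.5], [0.5], caliper=0.1)
        smd = balance_check([rec], [rec], m)
        assert (smd["smd"] == 0).all()
        assert smd["degenerate"].all()

    def test_empty_matching_rejected(self):
        rec = StudyRecord(age=60.0, sex=1, device_used=1, cecal_intubation=0.9, success=1)
        empty = match([0.01], [0.99], caliper=1e-6)
        with pytest.raises(ValueError):
            balance_check([rec], [rec], empty)
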