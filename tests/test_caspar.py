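"""CASPAR aging-rate model: lifespan fit, marginals, regimes, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from cagepheno import caspar as csp
from cagepheno import synth
from cagepheno.experiments import make_caspar_cohort


@pytest.fixture(scope="module")
def reference():
    recs = synth.simulate_lifespans(2000, np.log(25.0), 0.25, [0.0], 1e6,
                                    seed=11)
    return csp.fit_reference_lifespan(recs)


class TestReferenceLifespan:
    def test_complete_sample_recovery_within_2se(self):
        mu, s = float(np.log(25.0)), 0.25
        recs = synth.simulate_lifespans(2000, mu, s, [0.0], 1e6, seed=1)
        ref = csp.fit_reference_lifespan(recs)
        se = csp.observed_information_se(ref, recs)
        assert abs(ref.location - mu) < 2 * se[0]
        assert abs(ref.scale - s) < 2 * se[1]

    def test_truncated_censored_recovery(self):
        """Left truncation + right censoring leave the MLE consistent."""
        mu, s = float(np.log(25.0)), 0.25
        errs = []
        for rep in range(20):
            recs = synth.simulate_lifespans(
                1000, mu, s, [3.0, 7.0, 14.0, 21.0, 25.0], 15.0, seed=100 + rep)
            ref = csp.fit_reference_lifespan(recs)
            errs.append(ref.location - mu)
        assert abs(np.mean(errs)) < 0.02

    def test_all_censored_raises(self):
        recs = [synth.LifespanRecord("m0", 3.0, 9.0, "censored")]
        with pytest.raises(ValueError):
            csp.fit_reference_lifespan(recs)


class TestRemainingLife:
    def test_age_zero_equals_unconditional(self, reference):
        y = np.array([10.0, 25.0, 40.0])
        from scipy import stats
        g = stats.gumbel_r(reference.location, reference.scale)
        uncond = g.logpdf(np.log(y)) - np.log(y)
        assert np.allclose(csp.remaining_life_logdensity(reference, 0.0, y),
                           uncond)

    def test_density_normalizes(self, reference):
        # integrate on the log-remaining-life scale where the density is
        # smooth, to quadrature accuracy
        for age in (6.0, 30.0):
            val, err = quad(lambda u: np.exp(
                csp.log_remaining_logdensity(reference, age, u)),
                -25.0, np.log(1e6), limit=800, epsabs=1e-10, epsrel=1e-10)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_expected_remaining_life_decreases_with_age(self, reference):
        def expect(age):
            val, _ = quad(lambda y: y * np.exp(
                csp.remaining_life_logdensity(reference, age, y)),
                1e-9, 300.0, limit=500)
            return val
        assert expect(6.0) > expect(30.0)

    def test_invalid_inputs_raise(self, reference):
        with pytest.raises(ValueError):
            csp.remaining_life_logdensity(reference, 10.0, -1.0)


class TestGaussianMarginal:
    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_closed_form_matches_quadrature(self, m):
        rng = np.random.default_rng(m)
        b = 1.0 + 0.4 * rng.standard_normal(m)
        cf = csp.gaussian_marginal_loglik(b, 0.04, 1.0)
        q = csp.gaussian_marginal_quadrature(b, 0.04, 1.0)
        assert abs(cf - q) < 1e-8

    def test_single_run_is_convolution(self):
        from scipy import stats
        b = 1.37
        sb2, se2 = 0.09, 1.0
        expect = stats.norm.logpdf(b, 1.0, np.sqrt(sb2 + se2))
        assert csp.gaussian_marginal_loglik([b], sb2, se2) == pytest.approx(
            expect, abs=1e-12)

    def test_small_sigma_beta_collapses_prior(self):
        b = np.array([1.2, 0.9, 1.1])
        from scipy import stats
        limit = stats.norm.logpdf(b, 1.0, 1.0).sum()
        val = csp.gaussian_marginal_loglik(b, 1e-12, 1.0)
        assert val == pytest.approx(limit, abs=1e-6)


class TestFitting:
    def test_noise_features_give_no_signal(self, reference):
        rng = np.random.default_rng(0)
        n_mice = 50
        death = np.exp(rng.gumbel(np.log(25.0), 0.25, n_mice))
        X, ages, ttd, midx = [], [], [], []
        for j in range(n_mice):
            for _ in range(2):
                a = rng.uniform(3.0, max(death[j] * 0.9, 4.0))
                X.append(rng.standard_normal(6))
                ages.append(a)
                ttd.append(death[j] - a)
                midx.append(j)
        sel = np.asarray(ttd) > 0
        data = csp.CasparData(np.asarray(X)[sel], np.asarray(ages)[sel],
                              np.asarray(ttd)[sel], np.asarray(midx)[sel],
                              [f"m{j}" for j in range(n_mice)],
                              [f"f{i}" for i in range(6)])
        # hold out mice to measure test-set correlation
        test_mask = np.isin(data.mouse_index, np.arange(40, 50))
        tr = csp._subset(data, ~test_mask)
        te = csp._subset(data, test_mask)
        cfg = csp.CasparConfig(sigma_beta_sq=9.0, n_rounds=60, seed=0)
        model = csp.fit_caspar(tr, reference, cfg)
        pred = model.predict_biological_age(te.X)
        r = np.corrcoef(pred, te.ages)[0, 1] if np.std(pred) > 0 else 0.0
        assert abs(r) < 2.0 / np.sqrt(len(te.ages)) + 0.15

    def test_training_objective_decreases(self, reference):
        data, _ = make_caspar_cohort(40, seed=3)
        cfg = csp.CasparConfig(sigma_beta_sq=9.0, n_rounds=60, seed=0)
        model = csp.fit_caspar(data, reference, cfg)
        tr = model.train_objective_trace
        assert tr[-1] < tr[0]

    def test_predictions_positive(self, reference):
        data, _ = make_caspar_cohort(30, seed=4)
        cfg = csp.CasparConfig(sigma_beta_sq=9.0, n_rounds=30, seed=0)
        model = csp.fit_caspar(data, reference, cfg)
        assert (model.predict_biological_age(data.X) > 0).all()

    def test_linear_learner_runs(self, reference):
        data, _ = make_caspar_cohort(30, seed=5)
        cfg = csp.CasparConfig(sigma_beta_sq=0.01, n_rounds=10,
                               learner="linear", seed=0)
        model = csp.fit_caspar(data, reference, cfg)
        pred = model.predict_biological_age(data.X)
        assert np.corrcoef(pred, data.ages)[0, 1] > 0.5

    def test_censored_mouse_excluded(self):
        values = pd.DataFrame({"f0": [1.0, 2.0]})
        meta = pd.DataFrame({"mouse_id": ["a", "b"], "age_months": [10.0, 12.0]})
        ls = pd.DataFrame({"mouse_id": ["a", "b"],
                           "event_age": [20.0, 22.0],
                           "event": ["died", "censored"]})
        data = csp.build_caspar_data(values, meta, ls)
        assert data.mouse_ids == ["a"]


class TestEvaluation:
    def test_splits_are_distinct_full_animal_holdouts(self):
        splits = csp.animal_splits([f"m{i}" for i in range(30)], 10, 0.1, seed=0)
        as_sets = [tuple(s.tolist()) for s in splits]
        assert len(set(as_sets)) == 10
        assert all(len(s) >= 2 for s in splits)

    def test_evaluation_table_finite(self, reference):
        data, _ = make_caspar_cohort(40, seed=6)
        cfg = csp.CasparConfig(n_rounds=25, n_splits=3, seed=0)
        table = csp.evaluate_splits(data, reference, [0.5, 5.0], cfg)
        assert set(table["sigma_beta"]) == {0.5, 5.0}
        assert np.isfinite(table[["mean_r_age", "mean_r_ttd",
                                  "mean_R2_age", "mean_R2_ttd"]].to_numpy()).all()
        per = table.attrs["per_split"]
        assert len(per) == 2 * 3

    def test_predicted_rates_table(self, reference):
        data, _ = make_caspar_cohort(25, seed=7)
        cfg = csp.CasparConfig(n_rounds=20, seed=0)
        model = csp.fit_caspar(data, reference, cfg)
        df = csp.predicted_rates(model, data)
        assert (df["beta_ij"] > 0).all()
        grp = df.groupby("mouse_id")["beta_ij"].mean()
        merged = df.drop_duplicates("mouse_id").set_index("mouse_id")["beta_j"]
        assert np.allclose(grp[merged.index], merged)


class TestFeatureImportance:
    def test_untrained_model_empty(self, reference):
        cfg = csp.CasparConfig()
        model = csp.CasparModel(reference, cfg)
        with pytest.raises(ValueError):
            model.predict_biological_age(np.zeros((1, 3)))
        assert len(csp.feature_importance(model)) == 0

    def test_informative_features_ranked_top(self, reference):
        """Only the age/rate-linked features carry signal; they dominate
        gain-based importance."""
        data, _ = make_caspar_cohort(80, seed=8, n_noise=5)
        cfg = csp.CasparConfig(sigma_beta_sq=9.0, n_rounds=80, seed=0)
        model = csp.fit_caspar(data, reference, cfg)
        imp = csp.feature_importance(model, top_n=5)
        informative = {"f0", "f1", "f2", "f3", "f4"}
        top3 = set(imp["feature"].head(3))
        assert top3 <= informative
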