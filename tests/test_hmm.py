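"""Robust HMM: EM behavior, recovery, robustness states, labeling."""

import numpy as np
import pandas as pd
import pytest

from cagepheno import hmm as hmm_mod
from cagepheno import synth
from cagepheno.experiments import separated_state_config, simulate_separated_runs
from cagepheno.hmm import HMM_CHANNELS


class TestEM:
    def test_loglik_monotone(self, sep3):
        trace = np.array(sep3["model"].loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * abs(trace[0]))

    def test_posteriors_sum_to_one(self, sep3):
        seq = hmm_mod.decode(sep3["model"], sep3["runs"][0])
        from cagepheno.hmm import _emission_loglik, _fb_run, prepare_run
        p = prepare_run(sep3["runs"][0])
        ll = _emission_loglik(sep3["model"], p["X"], p["zero"], p["obs"],
                              p["analyzer"])
        gamma, _, _ = _fb_run(sep3["model"], ll)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_single_state_emission_equals_mean(self):
        """With one state and no robustness states, the EM fixed point for
        the emission location is the channel-wise mean of nonzero cells."""
        rng = np.random.default_rng(0)
        n = 600
        rows = pd.DataFrame(
            {c: 2.0 + 0.3 * rng.standard_normal(n) for c in synth.BASE_CHANNELS})
        rows.insert(0, "light", np.ones(n, dtype=int))
        rows.insert(0, "timestamp", np.arange(n) * 3.0)
        run = synth.RawRun("m", 1, "a0", 100.0, rows)
        model = hmm_mod.fit_robust_hmm([run], 1, robust_states=False,
                                       n_restarts=1, max_iter=20, seed=0,
                                       learn_offsets=False)
        X = run.rows[HMM_CHANNELS].to_numpy(float).copy()
        from cagepheno.hmm import _LOG1P_IDX
        X[:, _LOG1P_IDX] = np.log1p(X[:, _LOG1P_IDX])
        assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-6)

    def test_all_masked_raises(self, sep3):
        run = sep3["runs"][0]
        bad = synth.RawRun(run.mouse_id, run.run_number, run.analyzer_id,
                           run.start_age_days, run.rows)
        bad.qc_mask = pd.DataFrame(
            np.ones((len(run.rows), 14), dtype=np.int8),
            columns=synth.BASE_CHANNELS)
        with pytest.raises(ValueError):
            hmm_mod.fit_robust_hmm([bad], 2, seed=0)


class TestRecovery:
    def test_transition_matrix_recovery(self, sep3):
        model = sep3["model"]
        config = sep3["config"]
        cols = [synth.BASE_CHANNELS.index(c) for c in HMM_CHANNELS]
        perm = hmm_mod.match_states(model, config.state_means[:, cols])
        T_hat = model.transition_matrix[:3, :3]
        T_hat = T_hat / T_hat.sum(axis=1, keepdims=True)
        T_hat = T_hat[np.ix_(perm, perm)]
        assert np.abs(T_hat - config.transition_light).max() <= 0.05

    def test_analyzer_offset_recovery(self, sep3):
        model = sep3["model"]
        for a, true in sep3["offsets"].items():
            assert np.abs(model.analyzer_offsets[a] - true).max() <= 0.05

    def test_decode_ari(self, sep3):
        from sklearn.metrics import adjusted_rand_score
        aris = [adjusted_rand_score(r.truth["states"],
                                    hmm_mod.decode(sep3["model"], r).states)
                for r in sep3["runs"]]
        assert np.mean(aris) >= 0.9

    def test_label_permutation_invariance(self, sep3):
        """Relabeling generative states leaves the decoded ARI unchanged."""
        from sklearn.metrics import adjusted_rand_score
        r = sep3["runs"][0]
        seq = hmm_mod.decode(sep3["model"], r).states
        truth = r.truth["states"]
        perm = np.array([2, 0, 1])
        assert adjusted_rand_score(truth, seq) == pytest.approx(
            adjusted_rand_score(perm[truth], seq))


class TestRobustnessStates:
    def test_spurious_zero_bin_decoded_censored(self, sep3):
        model = sep3["model"]
        run = sep3["runs"][0]
        rows = run.rows.copy()
        # zero every channel in a block of bins amid normal activity
        for c in HMM_CHANNELS:
            rows.loc[100:104, c] = 0.0
        bad = synth.RawRun(run.mouse_id, run.run_number, run.analyzer_id,
                           run.start_age_days, rows)
        seq = hmm_mod.decode(model, bad)
        cen = model.censored_index
        assert np.all(seq.states[101:104] == cen)
        assert np.all(seq.posterior[101:104] > 0.5)

    def test_faults_absorbed_emissions_stable(self):
        """With robustness states, planted sensor bursts are absorbed by
        the broad noise state and the behavioral emission locations stay
        near their fault-free estimates; without robustness states the
        bursts contaminate the state means.  (Spurious zeros never touch
        the Gaussian locations in either model because exact zeros carry
        their own point mass.)"""
        config = separated_state_config(n_states=3, run_length_days=2)
        offsets = {"a0": np.zeros(5)}
        runs = simulate_separated_runs(config, 4, 1, offsets, seed=21)
        faulty = [synth.inject_sensor_faults(
            r, {}, {c: 0.05 for c in synth.BASE_CHANNELS}, seed=31 + i,
            burst_scale=6.0)
            for i, r in enumerate(runs)]
        cols = [synth.BASE_CHANNELS.index(c) for c in HMM_CHANNELS]
        ref = hmm_mod.fit_robust_hmm(runs, 3, n_restarts=1, max_iter=25,
                                     seed=0, learn_offsets=False)
        rob = hmm_mod.fit_robust_hmm(faulty, 3, n_restarts=1, max_iter=25,
                                     seed=0, learn_offsets=False)
        plain = hmm_mod.fit_robust_hmm(faulty, 3, robust_states=False,
                                       n_restarts=1, max_iter=25, seed=0,
                                       learn_offsets=False)
        true_means = config.state_means[:, cols]

        def matched_error(model):
            perm = hmm_mod.match_states(model, true_means)
            est = model.means[:3][perm]
            ref_est = ref.means[:3][hmm_mod.match_states(ref, true_means)]
            return np.abs(est - ref_est).mean()

        assert matched_error(rob) < matched_error(plain)

    def test_serialization_roundtrip(self, sep3):
        model = sep3["model"]
        clone = hmm_mod.RobustHMM.from_json(model.to_json())
        assert np.allclose(clone.transition_matrix, model.transition_matrix)
        assert np.allclose(clone.means, model.means)
        r = sep3["runs"][0]
        assert np.array_equal(hmm_mod.decode(clone, r).states,
                              hmm_mod.decode(model, r).states)


class TestSelection:
    def test_one_state_data_selects_one(self):
        config = separated_state_config(n_states=1, run_length_days=1)
        offsets = {"a0": np.zeros(5)}
        runs = simulate_separated_runs(config, 6, 2, offsets, seed=41)
        res = hmm_mod.select_n_states(runs[:8], runs[8:], k_range=[1, 2, 3],
                                      seed=0, n_restarts=1, max_iter=15)
        assert res["selected"] == 1

    def test_empty_k_range_raises(self, sep3):
        with pytest.raises(ValueError):
            hmm_mod.select_n_states(sep3["runs"][:1], sep3["runs"][1:2],
                                    k_range=[], seed=0)


class TestLabeling:
    def test_six_state_labels_match_design(self):
        """Synthetic profiles built to mimic the six behavioral states are
        labeled by the deterministic rule."""
        model = _label_fixture()
        labels = hmm_mod.label_states(model)
        assert labels[:6] == ["Sleep", "Rest", "Eat", "EatDrink", "Run",
                              "Active"]
        assert labels[6:] == ["Censored", "Noise"]

    def test_non_six_state_generic_labels(self, sep3):
        labels = hmm_mod.label_states(sep3["model"])
        assert labels[:3] == ["state_1", "state_2", "state_3"]


def _label_fixture():
    means, sds = synth.default_state_profiles()
    cols = [synth.BASE_CHANNELS.index(c) for c in HMM_CHANNELS]
    m = means[:, cols].copy()
    from cagepheno.hmm import _LOG1P_IDX
    m[:, _LOG1P_IDX] = np.log1p(m[:, _LOG1P_IDX])
    K = 8
    C = len(HMM_CHANNELS)
    full_m = np.zeros((K, C))
    full_m[:6] = m
    return hmm_mod.RobustHMM(
        6, True, np.full(K, 1 / K), np.full((K, K), 1 / K),
        full_m, np.full((K, C), 0.1), np.full((K, C), 1e-6),
        {}, np.ones(K, dtype=bool))
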