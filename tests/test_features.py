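"""Feature engine: catalog, corrections, bouts, extraction, trend filter."""

import numpy as np
import pandas as pd
import pytest

from cagepheno import features as feat
from cagepheno import synth
from cagepheno.hmm import StateSequence
from cagepheno.synth import BASE_CHANNELS, BINS_PER_DAY


def _toy_run(n_days=2, seed=0, states=None):
    """Fully observed run with known per-state channel values."""
    rng = np.random.default_rng(seed)
    n = n_days * BINS_PER_DAY
    if states is None:
        states = rng.integers(0, 6, n)
    rows = pd.DataFrame({c: np.ones(n) for c in BASE_CHANNELS})
    # per-state deterministic values for a few channels
    rows["VO2"] = 1.0 + 0.2 * states
    rows["Food"] = 0.01 * states
    rows["WheelMeters"] = np.where(states == 4, 50.0, 0.0)
    rows["BodyMass"] = 31.0
    rows.insert(0, "light", ((np.arange(n) % BINS_PER_DAY) < 240).astype(int))
    rows.insert(0, "timestamp", np.arange(n) * 3.0)
    run = synth.RawRun("m0", 1, "a0", 100.0, rows)
    seq = StateSequence("m0_r01", states, np.ones(n))
    return run, seq, states


class TestCatalog:
    def test_default_catalog_has_309_unique_features(self):
        cat = feat.build_catalog()
        names = [d.name for d in cat]
        assert len(cat) == 309
        assert len(set(names)) == 309

    def test_family_partition(self):
        from collections import Counter
        counts = Counter(d.family for d in feat.build_catalog())
        assert counts == {"overall": 22, "state_conditioned": 96,
                          "time_binned": 132, "transition_ratio": 44,
                          "bout": 15}


class TestExtraction:
    def test_vector_length(self):
        run, seq, _ = _toy_run()
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        assert feat.extract_features(t, cat).size == 309

    def test_state_conditioned_means_match_manual(self):
        run, seq, states = _toy_run(seed=1)
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        v = dict(zip([d.name for d in cat], feat.extract_features(t, cat)))
        for s_idx, s_name in enumerate(feat.DEFAULT_STATE_NAMES):
            manual = run.rows["VO2"].to_numpy()[states == s_idx].mean()
            assert v[f"VO2|{s_name}"] == pytest.approx(manual, abs=1e-12)

    def test_occupancy_weighted_consistency(self):
        """Occupancy-weighted state-conditioned means reproduce the
        overall mean exactly on fully observed runs."""
        run, seq, _ = _toy_run(seed=2)
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        v = dict(zip([d.name for d in cat], feat.extract_features(t, cat)))
        for m in ("VO2", "Food", "XBreak"):
            occ = np.array([v[f"occ_{s}"] for s in feat.DEFAULT_STATE_NAMES])
            cond = np.array([v[f"{m}|{s}"] for s in feat.DEFAULT_STATE_NAMES])
            ok = np.isfinite(cond)
            wavg = (occ[ok] * cond[ok]).sum() / occ[ok].sum()
            assert wavg == pytest.approx(v[f"mean_{m}"], abs=1e-9)

    def test_time_bin_coverage_weighted_consistency(self):
        run, seq, _ = _toy_run(seed=3)
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        v = dict(zip([d.name for d in cat], feat.extract_features(t, cat)))
        labels = [f"h{4*b:02d}-{4*b+4:02d}" for b in range(6)]
        # equal 4-h coverage on whole days: simple average reproduces overall
        bins = np.array([v[f"VO2@{lab}"] for lab in labels])
        assert bins.mean() == pytest.approx(v["mean_VO2"], abs=1e-9)

    def test_constant_channels_give_unit_ratios(self):
        run, seq, _ = _toy_run(seed=4)
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        v = dict(zip([d.name for d in cat], feat.extract_features(t, cat)))
        # Water is constant 1.0 everywhere in the toy run
        assert v["ratio_Water@lights_on"] == pytest.approx(1.0, abs=1e-12)
        assert v["ratio_Water@lights_off"] == pytest.approx(1.0, abs=1e-12)

    def test_unoccupied_state_is_missing_not_zero(self):
        run, seq, states = _toy_run(seed=5, states=np.zeros(2 * BINS_PER_DAY,
                                                            dtype=int))
        cat = feat.build_catalog()
        t = feat.measurement_table(run, seq)
        v = dict(zip([d.name for d in cat], feat.extract_features(t, cat)))
        assert np.isnan(v["VO2|Run"])
        assert v["occ_Run"] == 0.0


class TestBouts:
    def test_all_zero_channel_no_bouts(self):
        run, seq, _ = _toy_run(states=np.zeros(2 * BINS_PER_DAY, dtype=int))
        t = feat.measurement_table(run, seq)
        t["Food"] = 0.0
        bouts = feat.detect_bouts(t, feat.DEFAULT_BOUT_SPECS["feeding"])
        assert len(bouts) == 0

    def test_gap_merge_rule(self):
        run, seq, _ = _toy_run(states=np.zeros(2 * BINS_PER_DAY, dtype=int))
        t = feat.measurement_table(run, seq)
        t["Food"] = 0.0
        t.loc[10:14, "Food"] = 0.5
        t.loc[16:20, "Food"] = 0.5  # 1-bin gap at 15
        bouts = feat.detect_bouts(t, feat.BoutSpec("feeding", 0.01, max_gap=1,
                                                   min_duration=2))
        assert len(bouts) == 1
        assert bouts.iloc[0]["duration"] == 11

    def test_min_duration_filter(self):
        run, seq, _ = _toy_run(states=np.zeros(2 * BINS_PER_DAY, dtype=int))
        t = feat.measurement_table(run, seq)
        t["Food"] = 0.0
        t.loc[30, "Food"] = 0.5  # single-bin blip
        bouts = feat.detect_bouts(t, feat.BoutSpec("feeding", 0.01,
                                                   min_duration=2))
        assert len(bouts) == 0


class TestCorrections:
    def test_exposure_correction_removes_planted_slope(self):
        rng = np.random.default_rng(0)
        tables, rns = [], []
        for rn in range(1, 7):
            n = 480
            st = rng.integers(0, 2, n)
            t = pd.DataFrame({"state": st})
            # habituation: wheel declines 5%/run in state 1 only
            base = np.where(st == 1, 50.0, 0.0)
            t["WheelMeters"] = base * (1 - 0.05 * (rn - 1)) \
                + 0.5 * rng.standard_normal(n)
            tables.append(t)
            rns.append(rn)
        adj = feat.correct_exposure(tables, rns, measurements=["WheelMeters"])
        means = [a.loc[a["state"] == 1, "WheelMeters"].mean() for a in adj]
        slope = np.polyfit(rns, means, 1)[0]
        assert abs(slope) < 0.1  # raw slope is -2.5 per run

    def test_exposure_noop_without_planted_effect(self):
        rng = np.random.default_rng(1)
        tables = []
        for rn in range(1, 5):
            t = pd.DataFrame({"state": rng.integers(0, 2, 2000)})
            t["VO2"] = 2.0 + 0.1 * rng.standard_normal(2000)
            tables.append(t)
        adj = feat.correct_exposure(tables, [1, 2, 3, 4], measurements=["VO2"])
        for t, a in zip(tables, adj):
            assert np.abs(a["VO2"] - t["VO2"]).max() < 0.05

    def test_single_run_number_warns_noop(self):
        t = pd.DataFrame({"state": [0, 1], "VO2": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            adj = feat.correct_exposure([t, t], [1, 1], measurements=["VO2"])
        pd.testing.assert_frame_equal(adj[0], t)

    def test_mass_normalization_identity_at_reference(self):
        rng = np.random.default_rng(2)
        tables = [pd.DataFrame({"state": rng.integers(0, 2, 500),
                                "VO2": 2.0 + 0.1 * rng.standard_normal(500),
                                "VCO2": 1.8 + 0.1 * rng.standard_normal(500),
                                "EE": 0.5 + 0.05 * rng.standard_normal(500),
                                "VH2O": 1.0 + 0.1 * rng.standard_normal(500)})
                  for _ in range(4)]
        adj = feat.normalize_gas_for_mass(tables, [31.0] * 4)
        for t, a in zip(tables, adj):
            pd.testing.assert_frame_equal(t, a)

    def test_mass_normalization_decorrelates(self):
        rng = np.random.default_rng(3)
        masses = rng.uniform(20, 45, 30)
        tables = []
        for bm in masses:
            n = 300
            t = pd.DataFrame({"state": rng.integers(0, 2, n)})
            t["EE"] = 0.02 * bm + 0.02 * rng.standard_normal(n)
            for c in ("VO2", "VCO2", "VH2O"):
                t[c] = 1.0 + 0.05 * rng.standard_normal(n)
            tables.append(t)
        adj = feat.normalize_gas_for_mass(tables, list(masses))
        run_means = np.array([a["EE"].mean() for a in adj])
        r = np.corrcoef(run_means, masses)[0, 1]
        assert abs(r) < 0.05

    def test_rq_untouched(self, small_cohort):
        from cagepheno import hmm as hmm_mod
        from cagepheno import qc
        res = qc.qc_pipeline(small_cohort["runs"][:4])
        runs = res["runs"]
        model = hmm_mod.fit_robust_hmm(runs, 3, n_restarts=1, max_iter=10,
                                       seed=0)
        seqs = [hmm_mod.decode(model, r) for r in runs]
        tables = [feat.measurement_table(r, s, 3) for r, s in zip(runs, seqs)]
        before = [t["RQ"].copy() for t in tables]
        adj = feat.normalize_gas_for_mass(tables,
                                          [float(t["BodyMass"].mean())
                                           for t in tables])
        for b, a in zip(before, adj):
            assert np.array_equal(b.to_numpy(), a["RQ"].to_numpy(),
                                  equal_nan=True)


class TestAgeBins:
    def test_examples(self):
        bins = feat.assign_age_bins(np.array([0.0, 2.9, 3.0, 34.0, 40.0]))
        assert bins[0] == 0 and bins[1] == 0
        assert bins[2] == 1                      # half-open [3, 6)
        assert bins[3] == bins[4] == 11          # terminal pool 33-41
        assert feat.age_bin_label(11) == "[33,41)"

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            feat.assign_age_bins(np.array([-1.0]))


class TestTrendTests:
    def test_monotone_feature_has_tau_one(self):
        cat = feat.build_catalog()
        n = 40
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.standard_normal((n, 309)),
                              columns=[d.name for d in cat])
        ages = np.linspace(3, 30, n)
        values["mean_VO2"] = ages * 1.0  # strictly increasing
        values["mean_Food"] = 5.0        # constant -> missing
        meta = pd.DataFrame({"mouse_id": "m", "age_months": ages,
                             "run_number": 1, "cohort": "c0", "analyzer": "a0",
                             "body_mass": 31.0})
        fm = feat.FeatureMatrix(values, meta, cat)
        res = feat.age_trend_tests(fm).set_index("feature")
        assert res.loc["mean_VO2", "tau"] == pytest.approx(1.0)
        assert res.loc["mean_VO2", "significant"]
        assert np.isnan(res.loc["mean_Food", "tau"])


class TestTrendFilter:
    def test_lambda_zero_identity(self):
        X = np.random.default_rng(0).standard_normal((8, 4))
        assert np.array_equal(feat.trend_filter(X, 0.0), X)

    def test_lambda_infinity_linear(self):
        X = np.random.default_rng(1).standard_normal((10, 5))
        Y = feat.trend_filter(X, 1e7)
        assert np.abs(np.diff(Y, 2, axis=0)).max() < 1e-8

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            feat.trend_filter(np.zeros((5, 2)), -1.0)

    def test_common_kink_recovered(self):
        """A kink shared by many features at run 6 survives smoothing at a
        moderate penalty, and is the dominant curvature point."""
        rng = np.random.default_rng(2)
        T, p = 12, 20
        t = np.arange(T, dtype=float)
        base = np.where(t <= 6, t, 6 + 2.5 * (t - 6))  # slope change at 6
        X = base[:, None] * rng.uniform(0.5, 1.5, p)[None, :] \
            + 0.2 * rng.standard_normal((T, p))
        Y = feat.trend_filter(X, lam=1.0)
        D2 = np.linalg.norm(np.diff(Y, 2, axis=0), axis=1)
        assert int(np.argmax(D2)) + 1 == 6  # second-difference index offset

    def test_objective_not_worse_than_input(self):
        """The solver's objective at the solution is no worse than at the
        identity (a certificate the ADMM made progress on the convex
        program)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((9, 6))
        lam = 0.7

        def objective(Y):
            D2 = np.diff(Y, 2, axis=0)
            return 0.5 * ((X - Y) ** 2).sum() \
                + lam * np.linalg.norm(D2, axis=1).sum()

        Y = feat.trend_filter(X, lam)
        assert objective(Y) <= objective(X) + 1e-9

    def test_short_series_passthrough(self):
        X = np.random.default_rng(4).standard_normal((3, 4))
        assert np.array_equal(feat.trend_filter_mouse(X, 2.0), X)
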