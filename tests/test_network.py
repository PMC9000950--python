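"""Phenotype networks: nonparanormal, TVGL, clustering, resilience."""

import numpy as np
import pytest

from cagepheno import network as net


class TestResilience:
    def test_identity_is_zero(self):
        assert net.resilience(np.eye(7)) == 0.0

    def test_equicorrelation_closed_form(self):
        p, rho = 5, 0.5
        R = np.full((p, p), rho)
        np.fill_diagonal(R, 1.0)
        expected = 0.5 * ((p - 1) * np.log(1 - rho) + np.log(1 + (p - 1) * rho))
        assert net.resilience(R) == pytest.approx(expected, abs=1e-12)
        assert net.resilience(R) == pytest.approx(-0.837, abs=5e-4)

    def test_monotone_in_equicorrelation(self):
        vals = []
        for rho in np.linspace(0.0, 0.9, 10):
            R = np.full((4, 4), rho)
            np.fill_diagonal(R, 1.0)
            vals.append(net.resilience(R))
        assert np.all(np.diff(vals) < 0) or vals[0] == 0.0
        assert vals[0] == 0.0

    def test_bivariate_chain_pairwise_closed_form(self):
        """For an AR(1)-structured (tree) correlation matrix the negative
        multivariate MI decomposes over the chain's edges."""
        rho = 0.6
        p = 6
        R = rho ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        expected = 0.5 * (p - 1) * np.log(1 - rho ** 2)
        assert net.resilience(R) == pytest.approx(expected, abs=1e-10)

    def test_non_pd_raises(self):
        R = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            net.resilience(R)


class TestNonparanormal:
    def test_latent_correlation_recovery(self):
        rng = np.random.default_rng(0)
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        Z = rng.standard_normal((5000, 2)) @ np.linalg.cholesky(C).T
        R = net.nonparanormal_corr(Z)
        assert R[0, 1] == pytest.approx(0.6, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        C = np.array([[1.0, 0.45], [0.45, 1.0]])
        Z = rng.standard_normal((800, 2)) @ np.linalg.cholesky(C).T
        R1 = net.nonparanormal_corr(Z)
        R2 = net.nonparanormal_corr(
            np.column_stack([np.exp(Z[:, 0]), Z[:, 1] ** 3]))
        assert R1[0, 1] == pytest.approx(R2[0, 1], abs=1e-12)

    def test_independent_features_shrink_to_zero(self):
        rng = np.random.default_rng(2)
        R = net.nonparanormal_corr(rng.standard_normal((4000, 4)))
        off = R[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_feature_warns_and_zeroes(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        X[:, 1] = 2.0
        with pytest.warns(UserWarning):
            R = net.nonparanormal_corr(X)
        assert np.allclose(R[1, [0, 2]], 0.0)
        assert R[1, 1] == 1.0


class TestTVGL:
    def _corr(self, seed=0, p=12):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((p, p)) * 0.3
        prec = A @ A.T + 2.0 * np.eye(p)
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def test_large_sparsity_penalty_diagonal(self):
        R = self._corr()
        ps = net.fit_tvgl([R], lambda_sparsity=50.0, lambda_smooth=0.0,
                          max_iter=400)
        off = ps.precisions[0][~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_matches_graphical_lasso_oracle(self):
        from cagepheno.experiments import tvgl_glasso_agreement
        assert tvgl_glasso_agreement(seed=0)["max_diff"] < 1e-4

    def test_smoothness_penalty_monotone(self):
        rng = np.random.default_rng(4)
        R1 = self._corr(seed=5)
        noise = rng.standard_normal((12, 12)) * 0.05
        R2 = net.nearest_correlation(R1 + (noise + noise.T) / 2)
        diffs = []
        for lam_s in (0.0, 0.05, 0.3):
            ps = net.fit_tvgl([R1, R2], 0.1, lam_s, max_iter=600)
            diffs.append(np.abs(ps.precisions[0] - ps.precisions[1]).sum())
        assert diffs[0] >= diffs[1] >= diffs[2]

    def test_negative_penalty_raises(self):
        with pytest.raises(ValueError):
            net.fit_tvgl([np.eye(3)], -0.1, 0.0)

    def test_edge_list_weights_are_partial_correlations(self):
        R = self._corr(seed=6, p=5)
        ps = net.fit_tvgl([R], 0.01, 0.0, max_iter=600)
        edges = ps.edge_list([f"f{i}" for i in range(5)])
        P = ps.partial_correlations()[0]
        row = edges.iloc[0]
        i = int(row["source"][1:]); j = int(row["target"][1:])
        assert row["weight"] == pytest.approx(P[i, j])


class TestConsensusClustering:
    def test_perfect_blocks_recovered(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((150, 4))
        X = np.repeat(F, 5, axis=1) + 0.01 * rng.standard_normal((150, 20))
        cc = net.consensus_cluster(X, B=30, k_range=[2, 3, 4, 5, 6], seed=0)
        assert cc.k == 4
        from sklearn.metrics import adjusted_rand_score
        truth = np.repeat(np.arange(4), 5)
        assert adjusted_rand_score(truth, cc.assignments) == 1.0
        # consensus within blocks is (near) unity
        for c in range(4):
            mem = np.flatnonzero(cc.assignments == c)
            sub = cc.consensus[np.ix_(mem, mem)]
            assert sub.min() > 0.95

    def test_exemplars_belong_to_their_cluster(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((100, 3))
        X = np.repeat(F, 4, axis=1) + 0.3 * rng.standard_normal((100, 12))
        cc = net.consensus_cluster(X, B=20, k_range=[2, 3, 4], seed=1)
        for c in range(cc.k):
            members = np.flatnonzero(cc.assignments == c)
            assert any(e in members for e in cc.exemplars)

    def test_invalid_b_raises(self):
        with pytest.raises(ValueError):
            net.consensus_cluster(np.zeros((10, 4)), B=1)


class TestConnectivity:
    def _pset(self):
        # block precision: features {0,1} and {2,3} coupled within blocks
        prec = np.eye(4) * 2.0
        prec[0, 1] = prec[1, 0] = 0.8
        prec[2, 3] = prec[3, 2] = 0.8
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        return net.PrecisionSet([0], [R], [prec], 0.0, 0.0)

    def test_no_crossing_edges_zero_interconnectivity(self):
        ps = self._pset()
        conn = net.cluster_connectivity(ps, np.array([0, 0, 1, 1]))
        assert np.allclose(conn["inter_connectivity"].to_numpy(), 0.0)

    def test_sum_identity(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 6)) * 0.3
        prec = A @ A.T + 2.0 * np.eye(6)
        cov = np.linalg.inv(prec)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        ps = net.PrecisionSet([0], [R], [prec], 0.0, 0.0)
        assign = np.array([0, 0, 1, 1, 2, 2])
        conn = net.cluster_connectivity(ps, assign)
        P = np.abs(ps.partial_correlations()[0]).copy()
        np.fill_diagonal(P, 0.0)
        total_cross = sum(P[i, j] for i in range(6) for j in range(6)
                          if assign[i] != assign[j])
        assert conn["inter_connectivity"].to_numpy().sum() == pytest.approx(
            total_cross)

    def test_intra_resilience_nonpositive(self):
        ps = self._pset()
        conn = net.cluster_connectivity(ps, np.array([0, 0, 1, 1]))
        assert (conn["intra_resilience"].to_numpy() <= 1e-12).all()


class TestResilienceCurve:
    def test_age_strengthening_coupling_decreases_resilience(self):
        from cagepheno.experiments import resilience_aging_curve
        out = resilience_aging_curve(seed=0)
        assert out["monotone_decreasing"]
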