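import numpy as np
import pytest
from scipy.stats import norm

import scoredif as sd
from scoredif.estimation import QuadratureSpec
from scoredif.score_process import (
    ScoreMatrix,
    SingularCovarianceError,
    build_process,
    center,
    covariance,
    inverse_sqrt,
    score_contributions,
)


from oracles import dense_person_loglik


class TestScoreContributions:
    def test_mml_scores_sum_to_zero(self, null_2pl):
        ds, fitted = null_2pl
        S = score_contributions(ds.data, fitted)
        assert np.abs(S.values.sum(axis=0)).max() < 1e-3

    def test_map_scores_sum_to_minus_prior_gradient(self, map_3pl):
        ds, fitted = map_3pl
        S = score_contributions(ds.data, fitted)
        u = sd.log_prior_gradient(fitted.items, fitted.prior)
        assert np.abs(S.values.sum(axis=0) + u).max() < 1e-3

    @pytest.mark.parametrize("model", ["2PL", "3PL"])
    def test_rows_match_finite_differences_of_person_loglik(self, model):
        """Each row equals central finite differences (step 1e-6) of that
        person's log marginal likelihood on a dense quadrature grid."""
        cfg = sd.StudyConfig(model=model, n_persons=500, n_items=10, seed=17)
        ds = sd.generate_dataset(cfg, 1)
        quad = QuadratureSpec(n_points=801, lo=-8.0, hi=8.0)
        fitted = sd.fit(ds.data, model=model, method="MML", quadrature=quad)
        S = score_contributions(ds.data, fitted).values
        x = fitted.stacked()
        logw = norm.logpdf(quad.nodes)
        logw -= np.log(np.exp(logw).sum())
        h = 1e-6
        rng = np.random.default_rng(5)
        for i in rng.choice(ds.data.n_persons, 8, replace=False):
            y = ds.data.responses[i]
            for comp in range(x.size):
                hi, lo = x.copy(), x.copy()
                hi[comp] += h
                lo[comp] -= h
                fd = (
                    dense_person_loglik(y, hi, model, quad.nodes, logw)
                    - dense_person_loglik(y, lo, model, quad.nodes, logw)
                ) / (2 * h)
                assert abs(S[i, comp] - fd) / max(abs(fd), 1.0) < 1e-4

    def test_group_parameter_scores_sum_to_zero_at_optimum(self):
        cfg = sd.StudyConfig(model="2PL", n_persons=1000, n_items=10,
                             covariate="categorical", impact=True, seed=88)
        ds = sd.generate_dataset(cfg, 0)
        fitted = sd.fit(ds.data, model="2PL", method="MML", groups=True)
        G = sd.score_process.group_score_contributions(ds.data, fitted)
        assert G.shape == (1000, 2)
        assert np.abs(G.sum(axis=0)).max() < 1e-2


class TestCenter:
    def test_column_sums_vanish_and_idempotent(self, rng):
        S = ScoreMatrix(rng.normal(2.0, 1.0, size=(500, 6)))
        C = center(S)
        assert np.abs(C.values.sum(axis=0)).max() < 1e-10 * 500
        C2 = center(C)
        assert np.allclose(C2.values, C.values)

    def test_constant_column_becomes_zero(self):
        S = ScoreMatrix(np.full((20, 3), 7.0))
        assert np.all(center(S).values == 0.0)


class TestCovariance:
    def test_single_group_groupwise_equals_pooled(self, rng):
        C = center(ScoreMatrix(rng.normal(size=(200, 4))))
        pooled = covariance(C, "pooled")
        gw = covariance(C, "groupwise", groups=np.zeros(200, dtype=int))
        assert np.allclose(pooled.matrices[0], gw.matrices[0])

    def test_divisor_n_consistency_for_iid_standard_normals(self, rng):
        C = center(ScoreMatrix(rng.standard_normal((10000, 4))))
        V = covariance(C, "pooled").matrices[0]
        assert np.abs(V - np.eye(4)).max() < 0.1

    def test_zero_column_raises_singular_error(self, rng):
        M = rng.normal(size=(100, 3))
        M[:, 1] = 0.0
        with pytest.raises(SingularCovarianceError):
            covariance(center(ScoreMatrix(M)), "pooled")

    def test_requires_centered_state(self, rng):
        with pytest.raises(ValueError):
            covariance(ScoreMatrix(rng.normal(size=(50, 2))), "pooled")


class TestInverseSqrt:
    def test_identity_and_diagonal(self):
        assert np.allclose(inverse_sqrt(np.eye(3)), np.eye(3))
        S = inverse_sqrt(np.diag([4.0, 9.0]))
        assert np.allclose(S, np.diag([0.5, 1.0 / 3.0]))

    def test_defining_property_on_random_pd(self, rng):
        A = rng.normal(size=(6, 6))
        V = A @ A.T + 0.5 * np.eye(6)
        S = inverse_sqrt(V)
        assert np.allclose(S, S.T)
        assert np.abs(S @ V @ S - np.eye(6)).max() < 1e-8

    def test_not_pd_raises(self):
        with pytest.raises(SingularCovarianceError):
            inverse_sqrt(np.diag([1.0, 0.0]))


class TestBuildProcess:
    def test_pooled_path_ends_at_zero(self, null_2pl):
        ds, fitted = null_2pl
        C = center(score_contributions(ds.data, fitted))
        proc = build_process(C, covariance(C, "pooled"), ds.covariate)
        assert np.all(proc.path[0] == 0.0)
        assert np.abs(proc.path[-1]).max() < 1e-8

    def test_two_person_hand_computation(self):
        C = ScoreMatrix(np.array([[1.0], [-1.0]]), "centered")
        cov = sd.CovarianceEstimate("pooled", {0: np.eye(1)}, {0: np.eye(1)})
        proc = build_process(C, cov, np.array([0.0, 1.0]))
        assert np.allclose(proc.path[:, 0], [0.0, 1.0 / np.sqrt(2), 0.0])

    def test_single_group_groupwise_equals_pooled_process(self, rng):
        C = center(ScoreMatrix(rng.normal(size=(300, 3))))
        covar = rng.uniform(20, 70, 300)
        g = np.zeros(300, dtype=int)
        p1 = build_process(C, covariance(C, "pooled"), covar)
        p2 = build_process(C, covariance(C, "groupwise", groups=g), covar, groups=g)
        assert np.allclose(p1.path, p2.path)

    def test_joint_permutation_invariance(self, rng):
        C = center(ScoreMatrix(rng.normal(size=(200, 2))))
        covar = rng.normal(size=200)
        proc = build_process(C, covariance(C, "pooled"), covar)
        perm = rng.permutation(200)
        Cp = ScoreMatrix(C.values[perm], "centered")
        procp = build_process(Cp, covariance(Cp, "pooled"), covar[perm])
        assert np.allclose(proc.path, procp.path, atol=1e-10)

    def test_groupwise_heterogeneous_path_does_not_end_at_zero(self, rng):
        # two groups with strongly different score variances
        n = 400
        g = np.repeat([0, 1], n // 2)
        vals = np.where(g[:, None] == 0, 0.3, 3.0) * rng.standard_normal((n, 2))
        C = center(ScoreMatrix(vals))
        cov = covariance(C, "groupwise", groups=g)
        proc = build_process(C, cov, np.arange(n, dtype=float), groups=g)
        assert np.abs(proc.path[-1]).max() > 1e-3

    def test_covariate_length_mismatch(self, rng):
        C = center(ScoreMatrix(rng.normal(size=(50, 2))))
        with pytest.raises(ValueError):
            build_process(C, covariance(C, "pooled"), np.arange(49))


def test_null_process_variance_tracks_brownian_bridge(rng):
    """For iid null scores the pooled process variance at interior t is
    close to t(1-t), the Brownian bridge marginal variance."""
    reps, n = 400, 300
    mid = np.empty(reps)
    quarter = np.empty(reps)
    for r in range(reps):
        C = center(ScoreMatrix(rng.standard_normal((n, 1))))
        proc = build_process(C, covariance(C, "pooled"), np.arange(n, dtype=float))
        mid[r] = proc.path[n // 2, 0]
        quarter[r] = proc.path[n // 4, 0]
    assert np.var(mid) == pytest.approx(0.25, abs=0.05)
    assert np.var(quarter) == pytest.approx(0.1875, abs=0.05)


def test_process_frame_and_plot(tmp_path, null_2pl):
    ds, fitted = null_2pl
    C = center(score_contributions(ds.data, fitted))
    proc = build_process(C, covariance(C, "pooled"), ds.covariate)
    df = sd.score_process.process_to_frame(proc)
    assert set(df.columns) == {"t", "component", "value", "group"}
    assert len(df) == (ds.data.n_persons + 1) * proc.n_params
    out = tmp_path / "process.png"
    sd.score_process.plot_process(proc, out)
    assert out.stat().st_size > 0
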