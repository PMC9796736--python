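import numpy as np
import pytest
from scipy.stats import chi2, kstest, kstwobign, spearmanr

import scoredif as sd
from scoredif.invariance_tests import (
    CategoricalBins,
    dm_statistic,
    lmuo_statistic,
    pvalue_asymptotic_dm,
    pvalue_asymptotic_lmuo,
    pvalue_simulation,
    score_test,
)
from scoredif.score_process import CumulativeScoreProcess


def _process_from_path(path, groups=None):
    n = path.shape[0] - 1
    if groups is None:
        groups = np.zeros(n, dtype=int)
    return CumulativeScoreProcess(path, np.arange(n, dtype=float), groups, "pooled")


def _simulate_bridge_paths(reps, n, k, rng):
    """Discretized standard Brownian bridges via centered Gaussian sums."""
    s = rng.standard_normal((reps, n, k))
    s -= s.mean(axis=1, keepdims=True)
    path = np.cumsum(s, axis=1) / np.sqrt(n)
    zero = np.zeros((reps, 1, k))
    return np.concatenate([zero, path], axis=1)


class TestStatistics:
    def test_dm_zero_and_entrywise_max(self):
        zero = _process_from_path(np.zeros((11, 2)))
        assert dm_statistic(zero) == 0.0
        path = np.array([[0.0, 0.0], [0.1, -0.5], [0.3, 0.2]])
        assert dm_statistic(_process_from_path(path)) == 0.5

    def test_dm_matches_double_loop_oracle(self, rng):
        path = np.vstack([np.zeros(3), rng.normal(size=(40, 3))])
        best = 0.0
        for i in range(1, 41):
            for j in range(3):
                best = max(best, abs(path[i, j]))
        assert dm_statistic(_process_from_path(path)) == best

    def test_lmuo_zero_process(self):
        proc = _process_from_path(np.zeros((9, 2)))
        bins = CategoricalBins(np.array([0, 4, 8]))
        assert lmuo_statistic(proc, bins, weighted=True) == 0.0
        assert lmuo_statistic(proc, bins, weighted=False) == 0.0

    def test_lmuo_two_equal_halves_hand_value(self):
        # k=1, Psi(1/2) = g, Psi(1) = 0 -> weighted value g^2/.5 + g^2/.5
        n, g = 10, 0.7
        path = np.zeros((n + 1, 1))
        path[n // 2, 0] = g
        proc = _process_from_path(path)
        bins = CategoricalBins(np.array([0, n // 2, n]))
        assert lmuo_statistic(proc, bins) == pytest.approx(4 * g * g)
        assert lmuo_statistic(proc, bins, weighted=False) == pytest.approx(2 * g * g)

    def test_weighted_lmuo_is_chisquare_on_bridges(self):
        """Weighted LM_uo on simulated bridges follows chi-square(k(m-1)).

        The grid-level increments of a centered Gaussian random walk have
        exactly the bridge-increment covariance, so this check carries no
        discretization bias."""
        rng = np.random.default_rng(2026)
        reps, n, k, m = 5000, 240, 2, 3
        paths = _simulate_bridge_paths(reps, n, k, rng)
        bounds = np.array([0, 70, 160, n])
        stats = np.empty(reps)
        for r in range(reps):
            proc = _process_from_path(paths[r])
            stats[r] = lmuo_statistic(proc, CategoricalBins(bounds))
        assert kstest(stats, chi2(k * (m - 1)).cdf).pvalue > 0.01

    def test_dm_sign_flip_and_lmuo_permutation_invariance(self, rng):
        path = np.vstack([np.zeros(3), rng.normal(size=(30, 3))])
        proc = _process_from_path(path)
        flipped = path.copy()
        flipped[:, 1] *= -1.0
        assert dm_statistic(_process_from_path(flipped)) == dm_statistic(proc)
        bins = CategoricalBins(np.array([0, 10, 30]))
        permuted = path[:, [2, 0, 1]]
        assert lmuo_statistic(_process_from_path(permuted), bins) == pytest.approx(
            lmuo_statistic(proc, bins)
        )


class TestAsymptoticPvalues:
    def test_dm_at_zero_is_one(self):
        assert pvalue_asymptotic_dm(0.0, 1) == 1.0
        assert pvalue_asymptotic_dm(0.0, 5) == 1.0

    def test_dm_k1_matches_kolmogorov_distribution(self):
        p = pvalue_asymptotic_dm(1.358, 1)
        assert p == pytest.approx(0.0503, abs=5e-4)
        for x in (0.8, 1.0, 1.358, 1.63, 2.0):
            assert pvalue_asymptotic_dm(x, 1) == pytest.approx(
                kstwobign.sf(x), abs=1e-9
            )

    def test_dm_strictly_decreasing(self):
        grid = np.linspace(0.3, 3.0, 30)
        for k in (1, 3, 20):
            p = np.array([pvalue_asymptotic_dm(x, k) for x in grid])
            assert np.all(np.diff(p) <= 0)
            # strict wherever p is away from the floating-point ceiling at 1
            interior = p < 1.0 - 1e-12
            assert np.all(np.diff(p[interior]) < 0)

    def test_lmuo_chisquare_reference(self):
        assert pvalue_asymptotic_lmuo(0.0, 2, 2) == 1.0
        assert pvalue_asymptotic_lmuo(5.991, 2, 2) == pytest.approx(0.05, abs=2e-4)

    def test_dm_pvalues_uniform_on_bridge_maxima(self):
        """Asymptotic DM p-values of Brownian bridge suprema are U(0,1).

        Suprema are drawn from their exact law (scipy's independent
        Kolmogorov-distribution implementation); the maximum over a
        discretized simulated path would underestimate the continuous
        supremum at first order and bias the check."""
        rng = np.random.default_rng(2024)
        stats = kstwobign.rvs(size=5000, random_state=rng)
        pvals = np.array([pvalue_asymptotic_dm(x, 1) for x in stats])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_dm_pvalues_on_discretized_paths_mildly_conservative(self):
        """On a finite grid the DM p-values are slightly conservative
        (grid max <= continuous supremum) but close to uniform in mean."""
        rng = np.random.default_rng(2025)
        reps, n = 2000, 2000
        stats = np.empty(reps)
        chunk = 250
        for start in range(0, reps, chunk):
            paths = _simulate_bridge_paths(chunk, n, 1, rng)
            stats[start : start + chunk] = np.abs(paths[:, 1:, 0]).max(axis=1)
        pvals = np.array([pvalue_asymptotic_dm(x, 1) for x in stats])
        assert 0.5 <= pvals.mean() < 0.55


class TestSimulationEngine:
    def test_requires_minimum_replicates(self, rng):
        proc = _process_from_path(np.vstack([np.zeros(1), rng.normal(size=(20, 1))]))
        with pytest.raises(ValueError, match="R >= 99"):
            pvalue_simulation(proc, statistic="DM", R=50, seed=0)

    def test_extreme_statistic_attains_minimum_p(self):
        path = np.vstack([np.zeros(2), 100.0 * np.ones((50, 2))])
        path[-1] = 0.0
        proc = _process_from_path(path)
        res = pvalue_simulation(proc, statistic="DM", R=199, seed=1)
        assert res.pvalue == pytest.approx(1.0 / 200.0)

    def test_bit_reproducible_for_same_seed(self, rng):
        path = np.vstack([np.zeros(2), np.cumsum(rng.normal(size=(60, 2)), axis=0)])
        proc = _process_from_path(path)
        bins = CategoricalBins(np.array([0, 30, 60]))
        r1 = pvalue_simulation(proc, statistic="LM_uo", bins=bins, R=299, seed=7)
        r2 = pvalue_simulation(proc, statistic="LM_uo", bins=bins, R=299, seed=7)
        assert r1.pvalue == r2.pvalue
        r3 = pvalue_simulation(proc, statistic="LM_uo", bins=bins, R=299, seed=8)
        assert r1.pvalue != r3.pvalue or r1.value == r3.value

    def test_engines_agree_in_rank_across_null_datasets(self):
        """Pooled single-group processes: asymptotic and simulation p-values
        rank 50 null datasets the same way (Spearman rho > 0.8)."""
        p_asym, p_sim = [], []
        for r in range(50):
            cfg = sd.StudyConfig(model="2PL", n_persons=500, n_items=10,
                                 covariate="categorical", seed=909)
            ds = sd.generate_dataset(cfg, r)
            fitted = sd.fit(ds.data, model="2PL", method="MML")
            C = sd.center(sd.score_contributions(ds.data, fitted))
            proc = sd.build_process(C, sd.covariance(C, "pooled"), ds.covariate)
            bins = CategoricalBins.from_sorted_covariate(proc.covariate_sorted)
            p_asym.append(score_test(proc, "LM_uo", "asymptotic", bins).pvalue)
            p_sim.append(
                score_test(proc, "LM_uo", "simulation", bins, R=299, seed=r).pvalue
            )
        rho = spearmanr(p_asym, p_sim).statistic
        assert rho > 0.8


def test_test_result_serialization(tmp_path):
    res = sd.TestResult("DM", 1.2, 0.31, "asymptotic", k=4, n=100)
    out = tmp_path / "res.json"
    res.to_json(out)
    import json

    d = json.loads(out.read_text())
    assert d["statistic"] == "DM" and d["p"] == 0.31 and d["k"] == 4
    assert "invariance" in res.summary()
    with pytest.raises(ValueError):
        sd.TestResult("DM", 1.0, 1.5, "asymptotic", 1, 10)
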