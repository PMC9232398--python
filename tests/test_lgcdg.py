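"""Latent copula differential graph: bridge, tau, thresholds, LP estimator."""

import numpy as np
import pytest
from scipy import stats

from diffomics.lgcdg import (
    DeltaMatrix,
    bridge,
    bridge_invert,
    delta_edges,
    estimate_delta,
    estimate_thresholds,
    kendall_tau_matrix,
    latent_correlation,
    low_prevalence_genes,
    select_lambda,
)
from diffomics.simulate import SimulationConfig, simulate_cohort


def tau_a_bruteforce(x, y):
    """Pair-enumeration oracle for Kendall's tau-a (ties contribute 0)."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return 2.0 * s / (n * (n - 1))


class TestThresholds:
    def test_half_rate_gives_zero(self):
        d = np.array([[0], [1], [0], [1]])
        assert estimate_thresholds(d)[0] == pytest.approx(0.0)

    def test_normal_quantile(self):
        # one-rate 0.1587 ~= 1 - Phi(1) so the threshold sits near 1.0
        n = 10_000
        ones = int(round(0.1587 * n))
        d = np.array([1] * ones + [0] * (n - ones))[:, None]
        assert estimate_thresholds(d)[0] == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_column_winsorized(self):
        d = np.ones((50, 1), dtype=int)
        with pytest.warns(UserWarning, match="Winsorizing"):
            lam = estimate_thresholds(d)[0]
        assert lam == pytest.approx(stats.norm.ppf(0.01), abs=1e-12)


class TestKendallTau:
    def test_self_column_raw_value_and_diagonal(self):
        x = np.array([0, 0, 1])
        assert tau_a_bruteforce(x, x) == pytest.approx(2.0 / 3.0)
        tau = kendall_tau_matrix(x[:, None])
        assert tau[0, 0] == 1.0  # diagonal overridden by convention

    def test_matches_bruteforce_on_random_binary(self, rng):
        d = (rng.random((15, 4)) > 0.4).astype(int)
        tau = kendall_tau_matrix(d)
        for j in range(4):
            for k in range(j + 1, 4):
                assert tau[j, k] == pytest.approx(
                    tau_a_bruteforce(d[:, j], d[:, k]), abs=1e-12
                )

    def test_anti_aligned_columns(self):
        x = np.array([0, 1, 0, 1])
        d = np.stack([x, 1 - x], axis=1)
        expected = tau_a_bruteforce(x, 1 - x)  # -2/3 by enumeration
        assert expected == pytest.approx(-2.0 / 3.0)
        assert kendall_tau_matrix(d)[0, 1] == pytest.approx(expected)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        d = (rng.random((2000, 2)) > 0.5).astype(int)
        assert abs(kendall_tau_matrix(d)[0, 1]) <= 0.05


class TestBridge:
    def test_zero_tau_gives_zero_sigma(self):
        assert bridge_invert(0.0, 0.7, -1.3) == 0.0
        assert bridge(0.0, 0.7, -1.3) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_closed_form_at_zero_thresholds(self, rho):
        # Phi2(0,0;rho) = 1/4 + arcsin(rho)/(2 pi)  =>  tau = arcsin(rho)/pi
        tau = np.arcsin(rho) / np.pi
        assert bridge(rho, 0.0, 0.0) == pytest.approx(tau, abs=1e-12)
        assert bridge_invert(tau, 0.0, 0.0) == pytest.approx(rho, abs=1e-6)

    def test_strictly_increasing_in_sigma(self):
        grid = np.linspace(-0.95, 0.95, 39)
        for lj, lk in [(0.0, 0.0), (1.0, -0.5)]:
            vals = [bridge(s, lj, lk) for s in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))
        # extreme thresholds: increments shrink below double precision at
        # high sigma, so only nondecreasing can be asserted numerically
        vals = [bridge(s, -2.0, 2.0) for s in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_unattainable_tau_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            sigma = bridge_invert(0.9, 2.0, 2.0)
        assert sigma == pytest.approx(1.0 - 1e-6)


class TestLatentCorrelation:
    def test_recovery_from_lgcm_sample(self):
        cfg = SimulationConfig(
            n_samples=4000,
            p_genes=3,
            class_fraction=0.5,
            cnv_pairs=[(0, 1, -0.5, -0.5)],  # precision -0.5 -> correlation 0.5
            cnv_quantile=0.5,
            seed=13,
        )
        c = simulate_cohort(cfg)
        est = latent_correlation(c.cnv.to_numpy())
        # precision off-diagonal -0.5 => latent correlation +0.5 after inversion
        assert est.sigma_hat[0, 1] == pytest.approx(0.5, abs=0.08)
        assert abs(est.sigma_hat[0, 2]) <= 0.08

    def test_projection_keeps_pd_and_unit_diagonal(self, rng):
        d = (rng.random((60, 5)) > 0.6).astype(int)
        est = latent_correlation(d)
        vals = np.linalg.eigvalsh(est.sigma_hat)
        assert vals.min() >= 1e-3 - 1e-9
        assert np.allclose(np.diag(est.sigma_hat), 1.0)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            latent_correlation(np.array([[0, 2], [1, 0]]))


class TestEstimateDelta:
    def test_equal_inputs_give_zero(self):
        b = np.array([[1.0, 0.3], [0.3, 1.0]])
        dm = estimate_delta(b, b, 0.5)
        assert np.all(dm.delta == 0.0)

    def test_exact_lp_oracle_p2(self):
        # at lambda=0 the constraint forces b0 Delta b1 = b1 - b0 exactly;
        # with b0 = I the unique solution is inv(b0) - inv(b1)
        b0 = np.eye(2)
        b1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = np.linalg.inv(b0) - np.linalg.inv(b1)
        dm = estimate_delta(b1, b0, 0.0)
        assert np.allclose(dm.delta, expected, atol=1e-6)
        assert dm.delta[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_slack_constraint_gives_zero(self):
        b0 = np.eye(3)
        b1 = b0.copy()
        b1[0, 1] = b1[1, 0] = 0.2
        lam = np.abs(b1 - b0).max() + 0.01
        assert np.all(estimate_delta(b1, b0, lam).delta == 0.0)

    def test_class_swap_antisymmetry(self, rng):
        a = rng.normal(size=(4, 4))
        b0 = np.corrcoef(rng.normal(size=(50, 4)), rowvar=False)
        b1 = np.corrcoef(rng.normal(size=(50, 4)) @ (np.eye(4) + 0.2 * a), rowvar=False)
        d10 = estimate_delta(b1, b0, 0.05).delta
        d01 = estimate_delta(b0, b1, 0.05).delta
        assert np.allclose(d10, -d01, atol=1e-6)

    def test_sparsity_monotone_in_lambda(self, rng):
        b0 = np.corrcoef(rng.normal(size=(80, 5)), rowvar=False)
        b1 = np.corrcoef(rng.normal(size=(80, 5)), rowvar=False)
        sizes = [
            len(estimate_delta(b1, b0, lam).support)
            for lam in (0.0, 0.05, 0.1, 0.2, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            estimate_delta(np.eye(2), np.eye(2), -0.1)


class TestSelectLambda:
    def test_default_formula(self):
        lam = select_lambda(np.eye(10), np.eye(10), 500, 500)
        assert lam == pytest.approx(2 * np.sqrt(np.log(10) / 500), abs=1e-10)
        assert lam == pytest.approx(0.1357, abs=1e-3)

    def test_single_grid_value(self):
        assert select_lambda(np.eye(3), np.eye(3), 10, 10, grid=[0.07]) == 0.07


def test_delta_edges_thresholding():
    delta = np.zeros((3, 3))
    delta[0, 2] = delta[2, 0] = 0.4
    dm = DeltaMatrix(delta, 0.1, gene_ids=["A", "B", "C"])
    es = delta_edges(dm)
    assert es.pairs() == {("A", "C")}
    assert len(delta_edges(DeltaMatrix(np.zeros((3, 3)), 0.1))) == 0
    assert len(delta_edges(dm, tol=1.0)) == 0


def test_low_prevalence_detection():
    # all-zero and all-one columns are both degenerate for tau
    d = np.array([[0, 1, 1], [0, 1, 1], [0, 1, 0], [0, 1, 0]])
    assert list(low_prevalence_genes(d, min_count=2)) == [0, 1]
    assert list(low_prevalence_genes(d, min_count=1)) == [0, 1]
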