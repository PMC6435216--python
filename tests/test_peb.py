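"""Design matrix, PEB estimation, model reduction, comparison and averaging."""

import numpy as np
import pytest
from scipy import linalg
from scipy.stats import multivariate_normal

from dcmpeb.beliefs import GaussianBelief
from dcmpeb.design import DesignMatrix, build_design
from dcmpeb.peb import (
    Q0_SCALE,
    bayesian_model_reduction,
    bmc_over_subjects,
    default_beta_prior,
    enumerate_reduced_models,
    greedy_search_bma,
    group_peb,
    peb_estimate,
    predict_trajectories,
    score_reduced_models,
)


# -------------------------------------------------------------------------
# design matrix
# -------------------------------------------------------------------------


class TestDesign:
    def test_default_design_shape(self):
        X = build_design(60)
        assert X.matrix.shape == (60, 5)
        assert X.labels == ["constant", "dct2", "dct3", "dct4", "decay"]

    def test_decay_column_starts_at_one_and_decreases(self):
        X = build_design(30)
        d = X.column("decay")
        assert d[0] == 1.0
        assert np.all(np.diff(d) < 0.0)
        assert d[16] == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("W", [10, 20, 60])
    def test_dct_columns_orthonormal(self, W):
        X = build_design(W)
        D = X.matrix[:, 1:4]
        G = D.T @ D
        assert np.allclose(np.diag(G), 1.0)
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-10
        # and orthogonal to the constant
        assert np.abs(X.matrix[:, 0] @ D).max() < 1e-10

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 2 windows"):
            build_design(1)


# -------------------------------------------------------------------------
# Bayesian model reduction
# -------------------------------------------------------------------------


def _linear_evidence(A, y, prior, tau):
    C = A @ prior.cov @ A.T + np.eye(y.size) / tau
    lz = multivariate_normal(A @ prior.mean, C).logpdf(y)
    P = tau * A.T @ A + prior.precision()
    cov = linalg.inv(P)
    mean = cov @ (tau * A.T @ y + prior.precision() @ prior.mean)
    return lz, GaussianBelief(mean, cov)


class TestBMR:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.A = rng.standard_normal((9, 3))
        self.y = self.A @ rng.standard_normal(3) + 0.3 * rng.standard_normal(9)
        self.tau = 9.0
        self.full_prior = GaussianBelief(rng.standard_normal(3) * 0.2, np.diag([0.7, 1.2, 0.4]))
        _, self.full_post = _linear_evidence(self.A, self.y, self.full_prior, self.tau)

    def test_identity_reduction_is_exactly_zero(self):
        dF, post = bayesian_model_reduction(self.full_post, self.full_prior, self.full_prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(post.mean, self.full_post.mean)

    def test_delta_f_matches_direct_evidence_difference(self):
        reduced_prior = GaussianBelief(np.zeros(3), np.diag([0.7, 1e-6, 0.4]))
        lz_full, _ = _linear_evidence(self.A, self.y, self.full_prior, self.tau)
        lz_red, red_post = _linear_evidence(self.A, self.y, reduced_prior, self.tau)
        dF, post = bayesian_model_reduction(self.full_post, self.full_prior, reduced_prior)
        assert dF == pytest.approx(lz_red - lz_full, abs=1e-6)
        assert np.abs(post.mean - red_post.mean).max() < 1e-6

    def test_shrinking_one_prior_to_zero_pins_its_posterior(self):
        m1 = self.full_prior.mean.copy()
        cov = self.full_prior.cov.copy()
        cov[1, 1] = 1e-10
        _, post = bayesian_model_reduction(self.full_post, self.full_prior, GaussianBelief(m1, cov))
        assert post.mean[1] == pytest.approx(m1[1], abs=1e-4)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            bayesian_model_reduction(self.full_post, self.full_prior, GaussianBelief(np.zeros(2), np.eye(2)))


# -------------------------------------------------------------------------
# PEB estimation
# -------------------------------------------------------------------------


def _make_window_posteriors(rng, X, beta_true, prior, tau, gamma, G=None):
    """Linear first level: y_i = G theta_i + e; conjugate window posteriors."""
    B = prior.dim
    G = np.eye(B) * 3.0 if G is None else G
    Q1 = 16.0 * prior.precision()
    V = linalg.inv(Q0_SCALE * np.eye(B) + np.exp(-gamma) * Q1)
    posts, ys = [], []
    for i in range(X.W):
        m_i = np.kron(X.matrix[i], np.eye(B)) @ beta_true
        th = m_i + np.linalg.cholesky(V) @ rng.standard_normal(B)
        y = G @ th + rng.standard_normal(G.shape[0]) / np.sqrt(tau)
        P = tau * G.T @ G + prior.precision()
        C = linalg.inv(P)
        posts.append(GaussianBelief(C @ (tau * G.T @ y + prior.precision() @ prior.mean), C))
        ys.append(y)
    return posts, ys


class TestPebEstimate:
    def test_consensus_windows_recover_shared_mean(self):
        """Identical, highly informative windows + constant design -> beta = shared mean."""
        B, W = 2, 6
        prior = GaussianBelief(np.zeros(B), np.eye(B) / 16.0)
        shared = np.array([0.21, -0.14])
        post = GaussianBelief(shared, np.eye(B) * 1e-7)
        X = DesignMatrix(np.ones((W, 1)), ["constant"])
        res = peb_estimate([post.copy() for _ in range(W)], prior, X)
        assert np.abs(res.beta.mean - shared).max() < 1e-3

    def test_two_level_linear_oracle(self):
        """beta posterior equals one-shot inversion of the stacked joint model."""
        rng = np.random.default_rng(23)
        B, W = 2, 8
        X = DesignMatrix(np.column_stack([np.ones(W), np.linspace(-1, 1, W)]), ["constant", "slope"])
        prior = GaussianBelief(np.zeros(B), np.eye(B) / 16.0)
        beta_true = np.array([0.1, -0.3, 0.25, 0.15])
        tau, gamma = 200.0, 0.4
        G = rng.standard_normal((6, B))
        posts, ys = _make_window_posteriors(rng, X, beta_true, prior, tau, gamma, G)
        res = peb_estimate(posts, prior, X, gamma_prior=GaussianBelief([gamma], [[0.0]]))
        # direct joint-Gaussian solution of y = (I_W kron G)(X kron I_B) beta + noise
        Q1 = 16.0 * prior.precision()
        V = linalg.inv(Q0_SCALE * np.eye(B) + np.exp(-gamma) * Q1)
        XI = np.kron(X.matrix, np.eye(B))
        bigG = np.kron(np.eye(W), G)
        M = bigG @ XI
        Cy = bigG @ np.kron(np.eye(W), V) @ bigG.T + np.eye(6 * W) / tau
        yv = np.concatenate(ys)
        bp = default_beta_prior(prior, X.P)
        Pb = M.T @ linalg.inv(Cy) @ M + bp.precision()
        Cb = linalg.inv(Pb)
        mb = Cb @ (M.T @ linalg.inv(Cy) @ yv)
        assert np.abs(res.beta.mean - mb).max() < 1e-4
        assert np.abs(res.beta.cov - Cb).max() < 1e-4

    def test_decay_coefficient_sign_recovered(self):
        """A -0.5 decay effect on window means yields a negative estimate (20 seeds)."""
        B = 1
        X = build_design(20)
        prior = GaussianBelief(np.zeros(B), np.eye(B) / 16.0)
        beta_true = np.zeros(B * X.P)
        beta_true[(X.P - 1) * B] = -0.5
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            posts, _ = _make_window_posteriors(rng, X, beta_true, prior, tau=500.0, gamma=0.0)
            res = peb_estimate(posts, prior, X)
            hits += res.beta.mean[(X.P - 1) * B] < 0.0
        assert hits >= 18

    def test_window_count_mismatch_rejected(self):
        prior = GaussianBelief(np.zeros(2), np.eye(2))
        X = build_design(5)
        with pytest.raises(ValueError, match="design has"):
            peb_estimate([GaussianBelief(np.zeros(2), np.eye(2))] * 4, prior, X)


# -------------------------------------------------------------------------
# model space, pooling, averaging
# -------------------------------------------------------------------------


class TestModelSpace:
    def test_sixteen_models_from_four_regressors(self):
        ms = enumerate_reduced_models(4)
        assert ms.n_models == 16
        assert (~ms.inclusion.any(axis=1)).sum() == 1
        assert ms.null_index == 15  # the last model is the constant-only null
        assert ms.inclusion[0].all()

    def test_zero_regressors_gives_single_null(self):
        ms = enumerate_reduced_models(0)
        assert ms.n_models == 1
        assert ms.null_index == 0

    def test_pooling_single_subject_is_identity(self):
        lev = np.array([[0.0, 2.0, -1.0, 0.5]])
        ms = bmc_over_subjects(lev, enumerate_reduced_models(2))
        assert np.allclose(ms.pooled_logev, lev[0])

    def test_softmax_shift_invariance(self):
        base = np.array([[0.0, 3.0], [0.0, 3.0]])
        ms1 = bmc_over_subjects(base, enumerate_reduced_models(1))
        ms2 = bmc_over_subjects(base + np.array([[7.0], [0.0]]), enumerate_reduced_models(1))
        assert np.allclose(ms1.probabilities, ms2.probabilities)

    def test_two_subject_softmax_worked_example(self):
        lev = np.array([[0.0, 3.0], [0.0, 3.0]])
        ms = bmc_over_subjects(lev, enumerate_reduced_models(1))
        assert ms.probabilities[1] == pytest.approx(1.0 / (1.0 + np.exp(-6.0)))

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            bmc_over_subjects(np.array([[0.0, np.inf]]), enumerate_reduced_models(1))


def _toy_peb(beta_true, noise, seed, W=16, B=1):
    rng = np.random.default_rng(seed)
    X = build_design(W)
    prior = GaussianBelief(np.zeros(B), np.eye(B) / 16.0)
    G = np.eye(B) * 3.0 if B == 1 else rng.standard_normal((3 * B, B))
    posts, _ = _make_window_posteriors(rng, X, beta_true, prior, tau=1.0 / noise**2, gamma=0.0, G=G)
    return peb_estimate(posts, prior, X)


class TestGreedyBMA:
    def test_final_sweep_of_8_parameters_averages_256_models(self):
        beta = np.array([0.2, -0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -0.4, -0.3])
        peb = _toy_peb(beta, noise=0.05, seed=0, B=2)
        bma = greedy_search_bma(peb, final_sweep_size=8)
        assert bma.model_inclusion.shape[0] == 256
        assert np.isclose(bma.model_prob.sum(), 1.0)
        assert np.all((bma.Pp >= 0) & (bma.Pp <= 1))

    def test_null_effects_are_pruned(self):
        """Parameters with no second-level effect rarely keep Pp > .95 (20 seeds)."""
        ok = 0
        for seed in range(20):
            beta = np.array([0.3, 0.0, 0.0, 0.0, 0.0])  # constant only
            bma = greedy_search_bma(_toy_peb(beta, noise=0.05, seed=seed), final_sweep_size=5)
            ok += np.all(bma.Pp[1:] < 0.95)
        assert ok >= 18

    def test_overwhelming_effect_survives_with_correct_sign(self):
        beta = np.array([0.0, 1.0, 0.0, 0.0, 0.0])  # huge dct2 effect
        bma = greedy_search_bma(_toy_peb(beta, noise=0.01, seed=5), final_sweep_size=5)
        assert bma.Pp[1] > 0.95
        assert bma.mean[1] > 0.0

    def test_pp_consistent_with_model_probabilities(self):
        bma = greedy_search_bma(_toy_peb(np.array([0.2, 0.0, 0.3, 0.0, -0.4]), noise=0.05, seed=2), final_sweep_size=5)
        recomputed = (bma.model_prob[:, None] * bma.model_inclusion).sum(axis=0)
        assert np.allclose(bma.Pp, recomputed)


class TestGroupPeb:
    def _subject_pebs(self, n, beta_true, disp, seed, W=12, B=1, noise=0.05):
        rng = np.random.default_rng(seed)
        X = build_design(W)
        prior = GaussianBelief(np.zeros(B), np.eye(B) / 16.0)
        out = []
        for s in range(n):
            beta_s = beta_true + disp * rng.standard_normal(beta_true.size)
            posts, _ = _make_window_posteriors(rng, X, beta_s, prior, tau=1.0 / noise**2, gamma=0.0)
            out.append(peb_estimate(posts, prior, X))
        return out

    def test_single_subject_group_mean_matches_subject(self):
        # informative windows, so the subject posterior is dominated by its likelihood
        pebs = self._subject_pebs(1, np.array([0.2, 0.0, 0.0, 0.0, -0.3]), 0.0, seed=1, noise=0.005, W=20)
        g = group_peb(pebs)
        # a lone subject cannot inform the between-subject variance, so the
        # group mean is the subject mean up to mild random-effects shrinkage
        assert np.abs(g.beta.mean - pebs[0].beta.mean).max() < 0.1
        assert np.sign(g.beta.mean[-1]) == np.sign(pebs[0].beta.mean[-1])

    def test_identical_subjects_sharpen_the_group_posterior(self):
        pebs = self._subject_pebs(1, np.array([0.25, 0.0, 0.0, 0.0, -0.3]), 0.0, seed=3, noise=0.005, W=20)
        clones = [pebs[0]] * 6
        g = group_peb(clones)
        assert np.abs(g.beta.mean - pebs[0].beta.mean).max() < 0.05
        assert np.all(np.diag(g.beta.cov) < np.diag(pebs[0].beta.cov))

    def test_group_recovery_separates_conserved_from_subject_specific(self):
        """Shared decay -0.4: its group interval excludes 0; zero-mean DCT intervals include 0."""
        beta = np.array([0.0, 0.0, 0.0, 0.0, -0.4])
        disp = np.array([0.0, 0.2, 0.2, 0.2, 0.0])
        pebs = self._subject_pebs(12, beta, disp, seed=7)
        g = group_peb(pebs)
        m, sd = g.beta.mean, np.sqrt(np.diag(g.beta.cov))
        lo, hi = m - 1.645 * sd, m + 1.645 * sd
        assert hi[4] < 0.0  # decay interval excludes zero, negative
        # zero-group-mean DCT effects: intervals include 0 for the majority
        # (each has the nominal ~10% chance of excluding it)
        covered = sum(lo[k] < 0.0 < hi[k] for k in (1, 2, 3))
        assert covered >= 2

    def test_heterogeneous_designs_rejected(self):
        a = self._subject_pebs(1, np.zeros(5), 0.0, seed=1, W=12)
        b = self._subject_pebs(1, np.zeros(5), 0.0, seed=1, W=10)
        with pytest.raises(ValueError, match="share the second-level design"):
            group_peb([a[0], b[0]])


class TestTrajectories:
    def _bma_like(self, mean, cov, P, B):
        from dcmpeb.peb import BMAResult

        n = P * B
        return BMAResult(
            mean=np.asarray(mean, float),
            cov=np.asarray(cov, float),
            Pp=np.ones(n),
            model_inclusion=np.ones((1, n), bool),
            model_logev=np.zeros(1),
            model_prob=np.ones(1),
        )

    def test_constant_only_effect_gives_flat_trajectory(self):
        X = build_design(10)
        bma = self._bma_like([0.7, 0, 0, 0, 0], np.eye(5) * 1e-6, X.P, 1)
        traj = predict_trajectories(bma, X)
        assert np.allclose(traj.values, 0.7)

    def test_negative_decay_coefficient_increases_monotonically(self):
        X = build_design(24)
        bma = self._bma_like([0.0, 0, 0, 0, -0.5], np.eye(5) * 1e-6, X.P, 1)
        traj = predict_trajectories(bma, X)
        assert np.all(np.diff(traj.values[:, 0]) > 0.0)

    def test_band_halfwidth_is_quadratic_form(self):
        rng = np.random.default_rng(31)
        X = build_design(8)
        A = rng.standard_normal((5, 5))
        cov = A @ A.T / 10
        mean = rng.standard_normal(5) * 0.1
        from scipy.stats import norm

        traj = predict_trajectories(self._bma_like(mean, cov, X.P, 1), X)
        for w in range(8):
            x = X.matrix[w]
            half = norm.ppf(0.95) * np.sqrt(x @ cov @ x)
            assert traj.upper[w, 0] - traj.values[w, 0] == pytest.approx(half, rel=1e-6)
            assert traj.values[w, 0] == pytest.approx(x @ mean)
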