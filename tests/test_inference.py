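"""Variational EM: pseudo-observations, displacement smoothing, M-step,
and the full coordinate-ascent fit."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from driftssm.datasets import TrialDataset
from driftssm.geometry import (
    EmissionFrame,
    displacement_dim,
    displacement_to_emission,
    grassmann_distance,
    vec,
)
from driftssm.inference import (
    DisplacementPosterior,
    FitConfig,
    _eks_chain,
    build_pseudo_observations,
    estep_states,
    eks_displacements,
    expected_squared_increments,
    fit_smds,
    heldout_log_likelihood,
    mstep,
    predict_heldout_displacements,
)
from driftssm.lds import em_fit_lds, kalman_smooth, marginal_log_likelihood
from driftssm.smds import SMDSParams, sample_smds, simulation_config


def tiny_params(D=2, N=3, seed=0):
    rng = np.random.default_rng(seed)
    P = displacement_dim(D, N)
    U, _ = np.linalg.qr(rng.normal(size=(N, N)))
    return SMDSParams(
        A=0.8 * np.eye(D), b=np.zeros(D), Q=0.3 * np.eye(D),
        R=np.diag(rng.uniform(0.2, 0.5, N)),
        mu_x1=np.zeros(D), Sigma_x1=np.eye(D),
        frame=EmissionFrame(U, D), m_z=np.zeros(P), S_z=0.05 * np.eye(P),
        tau2=np.full(P, 1e-3),
    )


class TestEstepStates:
    def test_zero_displacement_reduces_to_pca_frame_lds(self):
        params = tiny_params()
        data, path, _ = sample_smds(params, 2, 3, 6, seed=1)
        z0 = np.zeros((2, params.P))
        groups, ll = estep_states(params, data, z0)
        C0 = params.frame.U_base[:, : params.D]
        ll_lds = marginal_log_likelihood(params.lds_view(C0), data)
        assert abs(ll - ll_lds) < 1e-9 * abs(ll_lds)

    def test_matches_per_trial_smoothing(self):
        params = tiny_params()
        data, path, _ = sample_smds(params, 2, 2, 5, seed=2)
        groups, ll = estep_states(params, data, path.z_blocks)
        for bi, sel, Y, post in groups:
            C = displacement_to_emission(path.z_blocks[bi], params.frame)
            for j, k in enumerate(sel):
                single = kalman_smooth(params.lds_view(C), data.trials[k])
                assert np.allclose(single.means[0], post.means[j])
                assert np.isclose(single.loglik[0], post.loglik[j])


class TestPseudoObservations:
    def test_identity_case(self):
        # R = I, one timestep, E[xx'] = I: R_hat = I, y_hat = vec(y x0')
        from driftssm.lds import StatePosterior

        D, N = 2, 3
        x0 = np.array([0.5, -1.0])
        y1 = np.array([1.0, 2.0, -0.5])
        post = StatePosterior(
            means=x0[None, None, :],
            covs=(np.eye(D) - np.outer(x0, x0))[None],  # makes E[xx'] = I
            cross=np.zeros((0, D, D)),
            loglik=np.zeros(1),
        )
        po = build_pseudo_observations([y1[None, None, :]], [post], np.eye(N))
        assert np.allclose(po.R_hat, np.eye(N * D))
        assert np.allclose(po.y_hat, vec(np.outer(y1, x0)))

    def test_quadratic_form_matches_expected_loglik(self):
        # the central correctness property: the pseudo-observation
        # Gaussian equals the expected log-likelihood up to a constant,
        # pinning the vec/Kronecker convention
        params = tiny_params()
        rng = np.random.default_rng(3)
        data, path, _ = sample_smds(params, 1, 1, 3, seed=4)
        groups, _ = estep_states(params, data, path.z_blocks)
        Ys = [Y for (_, _, Y, _) in groups]
        ps = [p for (_, _, _, p) in groups]
        po = build_pseudo_observations(Ys, ps, params.R)
        Rinv = np.linalg.inv(params.R)

        def expected_ll(z):
            C = displacement_to_emission(z, params.frame)
            tot = 0.0
            for Y, post in zip(Ys, ps):
                for m in range(Y.shape[0]):
                    for t in range(Y.shape[1]):
                        Exx = post.covs[t] + np.outer(post.means[m, t], post.means[m, t])
                        y = Y[m, t]
                        tot += -0.5 * (
                            y @ Rinv @ y
                            - 2 * y @ Rinv @ C @ post.means[m, t]
                            + np.trace(C.T @ Rinv @ C @ Exx)
                        )
            return tot

        mvn = multivariate_normal(po.y_hat, po.R_hat)
        diffs = [
            mvn.logpdf(vec(displacement_to_emission(z, params.frame))) - expected_ll(z)
            for z in path.z_blocks[0] + 0.3 * rng.normal(size=(20, params.P))
        ]
        assert np.ptp(diffs) < 1e-8

    def test_covariance_positive_definite(self):
        params = tiny_params(seed=5)
        data, _, _ = sample_smds(params, 1, 4, 6, seed=6)
        groups, _ = estep_states(params, data, np.zeros((1, params.P)))
        po = build_pseudo_observations(
            [Y for (_, _, Y, _) in groups], [p for (_, _, _, p) in groups], params.R
        )
        assert np.linalg.eigvalsh(po.R_hat).min() > 0


class TestDisplacementSmoother:
    def test_exact_for_affine_observation_map(self):
        # with g affine the EKS must coincide with the exact Kalman
        # smoother run on the same chain (identity dynamics)
        rng = np.random.default_rng(7)
        P, K, O = 3, 5, 4
        H = rng.normal(size=(O, P))
        c = rng.normal(size=O)
        Q = np.diag(rng.uniform(0.05, 0.2, P))
        m0, S0 = rng.normal(size=P), 0.4 * np.eye(P)
        ys = [rng.normal(size=O) for _ in range(K)]
        Rs = [np.diag(rng.uniform(0.2, 0.5, O)) for _ in range(K)]
        from conftest import condition_joint
        from driftssm.lds import LDSParams

        # common R across the chain so the explicit joint-Gaussian
        # conditioning oracle applies directly
        R0 = Rs[0]
        ms2, Ps2, cross2 = _eks_chain(ys, [R0] * K, lambda z: H @ z + c, lambda z: H, m0, S0, Q)
        p = LDSParams(A=np.eye(P), b=np.zeros(P), Q=Q, C=H, R=R0, mu_x1=m0, Sigma_x1=S0)
        y_shift = np.stack(ys) - c
        mu_o, S_o, _ = condition_joint(p, y_shift)
        assert np.max(np.abs(ms2.ravel() - mu_o)) < 1e-8
        for k in range(K):
            assert np.max(np.abs(Ps2[k] - S_o[k * P:(k + 1) * P, k * P:(k + 1) * P])) < 1e-8
        for k in range(K - 1):
            assert np.max(np.abs(cross2[k] - S_o[k * P:(k + 1) * P, (k + 1) * P:(k + 2) * P])) < 1e-8

    def test_single_block_matches_quadrature(self):
        # D=1, N=2: the displacement is a scalar; compare the Gaussian
        # EKS update with dense numerical integration of the true
        # (non-Gaussian) posterior
        params = tiny_params(D=1, N=2, seed=8)
        params.S_z = np.array([[1e-3]])
        params.m_z = np.array([0.3])
        data, path, _ = sample_smds(params, 1, 6, 8, seed=9)
        groups, _ = estep_states(params, data, params.m_z[None, :])
        po = build_pseudo_observations(
            [Y for (_, _, Y, _) in groups], [p for (_, _, _, p) in groups], params.R
        )
        zpost = eks_displacements(params, [po])
        grid = np.linspace(params.m_z[0] - 0.2, params.m_z[0] + 0.2, 4001)
        mvn = multivariate_normal(po.y_hat, po.R_hat)
        logp = np.array([
            mvn.logpdf(vec(displacement_to_emission(np.array([z]), params.frame)))
            - 0.5 * (z - params.m_z[0]) ** 2 / params.S_z[0, 0]
            for z in grid
        ])
        w = np.exp(logp - logp.max())
        w /= np.trapezoid(w, grid)
        mean_q = np.trapezoid(w * grid, grid)
        var_q = np.trapezoid(w * (grid - mean_q) ** 2, grid)
        assert abs(zpost.means[0, 0] - mean_q) < 5e-3
        assert abs(zpost.covs[0, 0, 0] - var_q) < 0.1 * var_q

    def test_rigid_chain_for_zero_drift_rate(self):
        # tau2 -> 0 with identical data in every block: all block
        # posteriors coincide
        params = tiny_params(seed=10)
        params.tau2 = np.full(params.P, 1e-14)
        data, _, _ = sample_smds(params, 1, 3, 5, seed=11)
        groups, _ = estep_states(params, data, np.zeros((1, params.P)))
        po = build_pseudo_observations(
            [Y for (_, _, Y, _) in groups], [p for (_, _, _, p) in groups], params.R
        )
        zpost = eks_displacements(params, [po, po, po])
        assert np.max(np.abs(zpost.means - zpost.means[0])) < 1e-6


class TestMStep:
    def test_tau2_posterior_mode_hand_calculation(self):
        # scalar z, K=3 blocks, IG(alpha=2, beta=0.1): mode =
        # (beta + 0.5*sum E[d^2]) / (alpha + 1 + (K-1)/2)
        params = tiny_params(D=1, N=2, seed=12)
        data, path, _ = sample_smds(params, 3, 2, 4, seed=13)
        groups, _ = estep_states(params, data, path.z_blocks)
        means = np.array([[0.1], [0.3], [0.2]])
        covs = np.array([[[0.02]], [[0.03]], [[0.01]]])
        cross = np.array([[[0.005]], [[0.004]]])
        zpost = DisplacementPosterior(means, covs, cross, np.arange(3))
        cfg = FitConfig(ig_alpha=2.0, ig_beta=0.1, tau2_clip=10.0)
        new, diag = mstep(groups, zpost, params, cfg)
        d1 = (0.3 - 0.1) ** 2 + 0.03 + 0.02 - 2 * 0.005
        d2 = (0.2 - 0.3) ** 2 + 0.01 + 0.03 - 2 * 0.004
        expected = (0.1 + 0.5 * (d1 + d2)) / (2.0 + 1.0 + 1.0)
        assert np.isclose(new.tau2[0], expected)
        assert np.isclose(expected_squared_increments(zpost)[0], d1 + d2)

    def test_tau2_clipping_binds(self):
        params = tiny_params(D=1, N=2, seed=14)
        data, path, _ = sample_smds(params, 3, 2, 4, seed=15)
        groups, _ = estep_states(params, data, path.z_blocks)
        zpost = DisplacementPosterior(
            np.array([[0.0], [5.0], [-5.0]]),
            np.full((3, 1, 1), 0.1),
            np.zeros((2, 1, 1)),
            np.arange(3),
        )
        cfg = FitConfig(tau2_clip=1e-3)
        new, diag = mstep(groups, zpost, params, cfg)
        assert new.tau2[0] == pytest.approx(1e-3)
        assert diag["clip_active"]

    def test_dynamics_update_matches_lds_mstep_without_drift(self):
        # with a single block and zero displacement, the dynamics/noise
        # updates must equal the plain LDS M-step on the same posteriors
        params = tiny_params(seed=16)
        data, _, _ = sample_smds(params, 1, 20, 10, seed=17)
        z0 = np.zeros((1, params.P))
        groups, _ = estep_states(params, data, z0)
        zpost = DisplacementPosterior(
            z0, 1e-8 * np.eye(params.P)[None], np.zeros((0, params.P, params.P)),
            np.zeros(1),
        )
        new, _ = mstep(groups, zpost, params, FitConfig())
        C0 = params.frame.U_base[:, : params.D]
        init = params.lds_view(C0)
        fitted, _ = em_fit_lds(data, params.D, init=init, max_iter=1)
        # one EM iteration from the same starting point yields the same
        # dynamics updates (emission fixed vs free differs only in C/R)
        assert np.allclose(new.A, fitted.A, atol=1e-8)
        assert np.allclose(new.b, fitted.b, atol=1e-8)
        assert np.allclose(new.Q, fitted.Q, atol=1e-8)


class TestFullFit:
    def test_stationary_data_matches_lds_loglik(self):
        # tau2 = 0 generator: the drift model's training LL ends within
        # 1% of plain LDS EM at the same dimension
        params, _ = simulation_config("main", n_trials=60)
        params.tau2 = np.zeros(params.P)
        params.S_z = np.zeros((params.P, params.P))
        data, _, _ = sample_smds(params, 12, 5, 30, seed=18)
        # run to convergence: the coordinate ascent can be transiently
        # non-monotone while R equilibrates on no-drift data
        fit = fit_smds(data, 2, FitConfig(max_iter=60))
        _, ll_smds = estep_states(fit.params, data, fit.z_post.means)
        _, trace = em_fit_lds(data, 2, max_iter=60)
        assert ll_smds > trace[-1] - 0.01 * abs(trace[-1])

    def test_recovers_drifting_subspaces(self):
        params, sizes = simulation_config("main", n_trials=150)
        data, path, _ = sample_smds(
            params, sizes["n_blocks"], sizes["trials_per_block"], sizes["T"], seed=19
        )
        fit = fit_smds(data, 2, FitConfig(max_iter=25))
        dists = [
            grassmann_distance(fit.emissions[k], path.C_blocks[k], normalized=True)
            for k in range(sizes["n_blocks"])
        ]
        assert np.median(dists) < 0.1

    def test_objective_proxy_no_large_decrease(self):
        params, sizes = simulation_config("main", n_trials=100)
        data, _, _ = sample_smds(
            params, sizes["n_blocks"], sizes["trials_per_block"], sizes["T"], seed=20
        )
        fit = fit_smds(data, 2, FitConfig(max_iter=20))
        tr = fit.elbo_trace
        rel_drop = np.diff(tr) / np.abs(tr[:-1])
        assert rel_drop.min() > -0.01

    def test_deterministic(self):
        params, _ = simulation_config("main", n_trials=30)
        data, _, _ = sample_smds(params, 6, 5, 15, seed=21)
        f1 = fit_smds(data, 2, FitConfig(max_iter=5))
        f2 = fit_smds(data, 2, FitConfig(max_iter=5))
        assert np.array_equal(f1.elbo_trace, f2.elbo_trace)
        assert np.array_equal(f1.z_post.means, f2.z_post.means)


class TestHeldout:
    def test_definition_on_training_block(self):
        # scoring a training block with its own fitted displacement is
        # exactly the LDS likelihood at h(z_hat)
        params, _ = simulation_config("main", n_trials=40)
        data, _, _ = sample_smds(params, 8, 5, 15, seed=22)
        fit = fit_smds(data, 2, FitConfig(max_iter=10))
        lab = 3
        sub = data.subset_blocks([lab])
        ll = heldout_log_likelihood(fit, sub)
        C = displacement_to_emission(fit.z_post.means[lab], fit.params.frame)
        assert np.isclose(ll, marginal_log_likelihood(fit.params.lds_view(C), sub))

    def test_interpolation_midpoint(self):
        z = np.array([[0.0, 1.0], [2.0, 3.0]])
        zpost = DisplacementPosterior(
            z, np.zeros((2, 2, 2)), np.zeros((1, 2, 2)), np.array([0, 2])
        )
        pred = predict_heldout_displacements(zpost, [1])
        assert np.allclose(pred, [[1.0, 2.0]])

    def test_extrapolation_uses_nearest_end(self):
        z = np.array([[0.0], [1.0]])
        zpost = DisplacementPosterior(
            z, np.zeros((2, 1, 1)), np.zeros((1, 1, 1)), np.array([2, 3])
        )
        with pytest.warns(UserWarning, match="nearest-end"):
            pred = predict_heldout_displacements(zpost, [0, 9])
        assert np.allclose(pred.ravel(), [0.0, 1.0])
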