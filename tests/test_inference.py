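import copy

import numpy as np
import pytest
from scipy.special import digamma, expit

import omifa
from omifa import inference as inf
from omifa.dataset import MultiOmicsDataset, ViewMatrix
from omifa.state import TrainingConfig
from omifa.trainer import initialize_model, train_once
from oracles import (
    gaussian_targets,
    naive_elbo_gaussian,
    naive_factor_update,
    naive_weight_update,
)


def _prepared_state(ds, k=3, seed=0, n_warm=3):
    """A state a few update sweeps past initialization (non-degenerate)."""
    cfg = TrainingConfig(K_initial=k, n_restarts=1)
    state = initialize_model(ds, cfg, seed=seed)
    for _ in range(n_warm):
        state.weights = inf.update_weights(state, ds, True)
        state.factors = inf.update_factors(state, ds)
        state.sparsity = inf.update_sparsity(state, cfg)
        state.ard = inf.update_ard(state, cfg)
        for m, v in enumerate(ds.views):
            if v.likelihood == "gaussian":
                state.noise[m] = inf.update_noise(state, ds, cfg, m)
    return state, cfg


def _targets(ds, state):
    return [
        gaussian_targets(v, state.noise[m].expectation, state.intercepts[m])
        for m, v in enumerate(ds.views)
    ]


class TestFactorUpdate:
    def test_matches_loop_oracle(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, _ = _prepared_state(ds, k=2)
        got = inf.update_factors(state, ds)
        ew = [w.expected_weight for w in state.weights]
        ew2 = [w.expected_weight_sq for w in state.weights]
        means, covs = naive_factor_update(ds, _targets(ds, state), ew, ew2)
        np.testing.assert_allclose(got.mean, means, atol=1e-8)
        np.testing.assert_allclose(got.cov, covs, atol=1e-8)

    def test_unobserved_sample_falls_back_to_prior(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        ds = copy.deepcopy(ds)
        for v in ds.views:
            v.mask[3, :] = False
        state, _ = _prepared_state(ds, k=2)
        fac = inf.update_factors(state, ds)
        np.testing.assert_allclose(fac.mean[3], 0.0, atol=1e-12)
        np.testing.assert_allclose(fac.cov[3], np.eye(2), atol=1e-12)

    def test_k1_closed_form_scalar_posterior(self):
        # K=1, one view: mean_n = (sum_d tau_d w_d y_nd) / (1 + sum_d tau_d E[w_d^2])
        rng = np.random.default_rng(5)
        n, d = 6, 4
        data = rng.standard_normal((n, d))
        ds = MultiOmicsDataset(
            views=[ViewMatrix(name="v", data=data, mask=np.ones((n, d), bool),
                              likelihood="gaussian")]
        )
        state, _ = _prepared_state(ds, k=1, n_warm=2)
        fac = inf.update_factors(state, ds)
        tau = state.noise[0].expectation
        w = state.weights[0].expected_weight[:, 0]
        w2 = state.weights[0].expected_weight_sq[:, 0]
        y = data - state.intercepts[0][None, :]
        denom = 1.0 + np.sum(tau * w2)
        for i in range(n):
            expected = np.sum(tau * w * y[i]) / denom
            assert fac.mean[i, 0] == pytest.approx(expected, abs=1e-10)
            assert fac.cov[i, 0, 0] == pytest.approx(1.0 / denom, abs=1e-12)


class TestWeightUpdate:
    def test_matches_loop_oracle(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, _ = _prepared_state(ds, k=2)
        got = inf.update_weights(state, ds, sparsity_active=True)
        for m, view in enumerate(ds.views):
            y, t = gaussian_targets(view, state.noise[m].expectation, state.intercepts[m])
            gamma, mu1, var1, ew = naive_weight_update(
                view, y, t,
                state.factors.mean, state.factors.cov,
                state.ard[m].expectation,
                state.sparsity[m].expectation_logit(),
                state.weights[m].expected_weight,
            )
            np.testing.assert_allclose(got[m].gamma, gamma, atol=1e-8)
            np.testing.assert_allclose(got[m].mean_given_included, mu1, atol=1e-8)
            np.testing.assert_allclose(got[m].var_given_included, var1, atol=1e-8)

    def test_zero_evidence_feature_falls_back_to_prior(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        ds = copy.deepcopy(ds)
        ds.views[0].mask[:, 2] = False
        state, cfg = _prepared_state(ds, k=2)
        got = inf.update_weights(state, ds, sparsity_active=True)
        sp = state.sparsity[0]
        expected_gamma = expit(digamma(sp.a) - digamma(sp.b))
        np.testing.assert_allclose(got[0].gamma[2], expected_gamma, atol=1e-10)
        np.testing.assert_allclose(got[0].mean_given_included[2], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            got[0].var_given_included[2], 1.0 / state.ard[0].expectation, atol=1e-12
        )

    def test_strong_evidence_gives_high_inclusion(self):
        # feature 0 is a noisy copy of the factor; with q(z) pinned at the
        # truth, the joint spike-and-slab update must include it (gamma > .99)
        # and match a hand-coded scalar posterior
        rng = np.random.default_rng(6)
        n = 60
        z = rng.standard_normal(n)
        data = np.column_stack([3.0 * z + 0.1 * rng.standard_normal(n),
                                rng.standard_normal(n)])
        ds = MultiOmicsDataset(
            views=[ViewMatrix(name="v", data=data, mask=np.ones((n, 2), bool),
                              likelihood="gaussian")]
        )
        cfg = TrainingConfig(K_initial=1)
        state = initialize_model(ds, cfg, seed=0)
        state.factors.mean[:, 0] = z
        state.factors.cov[:] = 1e-6 * np.eye(1)
        got = inf.update_weights(state, ds, sparsity_active=True)[0]
        assert got.gamma[0, 0] > 0.99
        # scalar oracle for the included feature
        tau = state.noise[0].expectation[0]
        y0 = data[:, 0] - state.intercepts[0][0]
        h = tau * np.sum(y0 * z)
        q = tau * np.sum(z**2 + 1e-6)
        lam = state.ard[0].expectation[0] + q
        sp = state.sparsity[0]
        logit = (digamma(sp.a[0]) - digamma(sp.b[0])
                 + 0.5 * np.log(state.ard[0].expectation[0])
                 - 0.5 * np.log(lam) + 0.5 * h**2 / lam)
        assert got.gamma[0, 0] == pytest.approx(expit(logit), abs=1e-10)
        assert got.mean_given_included[0, 0] == pytest.approx(h / lam, rel=1e-10)

    def test_burn_in_clamps_inclusion_to_one(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, _ = _prepared_state(ds, k=2)
        got = inf.update_weights(state, ds, sparsity_active=False)
        for wp in got:
            np.testing.assert_array_equal(wp.gamma, 1.0)


class TestConjugateUpdates:
    def test_ard_shrinks_inactive_factors(self, small_trained):
        model, ds, truth = small_trained
        # simulated truth has 3 factors; the trained ARD precisions of
        # retained factors stay moderate while a factor with near-zero slab
        # weights would be driven to huge precision
        state = copy.deepcopy(model.state)
        wp = state.weights[0]
        wp.mean_given_included[:, 0] = 1e-6
        wp.var_given_included[:, 0] = 1e-8
        wp.gamma[:, 0] = 1.0
        new = inf.update_ard(state, model.config)
        assert new[0].expectation[0] > 1e3
        assert new[0].expectation[0] > 100 * new[0].expectation[1]

    def test_ard_matches_loop_oracle(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, cfg = _prepared_state(ds, k=2)
        new = inf.update_ard(state, cfg)
        a0, b0 = cfg.ard_prior
        for m, wp in enumerate(state.weights):
            d, k = wp.gamma.shape
            for kk in range(k):
                ssum = 0.0
                for j in range(d):
                    g = wp.gamma[j, kk]
                    ssum += g * (wp.mean_given_included[j, kk] ** 2
                                 + wp.var_given_included[j, kk])
                    ssum += (1 - g) * wp.var_spike[kk]
                assert new[m].shape[kk] == pytest.approx(a0 + d / 2)
                assert new[m].rate[kk] == pytest.approx(b0 + ssum / 2, rel=1e-10)

    def test_sparsity_update_beta_counts(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, cfg = _prepared_state(ds, k=2)
        # all gamma = 1 -> E[theta] ~ 1 for large D; gamma = 0.5 -> 0.5
        d = state.weights[0].gamma.shape[0]
        state.weights[0].gamma[:] = 1.0
        new = inf.update_sparsity(state, cfg)
        assert new[0].expectation[0] == pytest.approx((1.0 + d) / (2.0 + d))
        state.weights[0].gamma[:] = 0.5
        new = inf.update_sparsity(state, cfg)
        np.testing.assert_allclose(new[0].expectation, 0.5, atol=1e-12)

    def test_noise_recovers_unit_residual_precision(self):
        # pure N(0,1) noise, no structure: E[tau] ~ 1 within 5%
        rng = np.random.default_rng(8)
        data = rng.standard_normal((200, 30))
        ds = MultiOmicsDataset(
            views=[ViewMatrix(name="v", data=data, mask=np.ones((200, 30), bool),
                              likelihood="gaussian")]
        )
        model = train_once(ds, TrainingConfig(K_initial=2, n_restarts=1,
                                              max_iterations=60), seed=0)
        etau = model.state.noise[0].expectation
        assert abs(np.median(etau) - 1.0) < 0.05

    def test_noise_update_ignores_masked_values(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, cfg = _prepared_state(ds, k=2)
        ns1 = inf.update_noise(state, ds, cfg, 0)
        ds2 = copy.deepcopy(ds)
        ds2.views[0].data = np.where(ds2.views[0].mask, ds2.views[0].data, -1e6)
        ns2 = inf.update_noise(state, ds2, cfg, 0)
        np.testing.assert_array_equal(ns1.rate, ns2.rate)


class TestElbo:
    def test_matches_term_by_term_loop_oracle(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, cfg = _prepared_state(ds, k=2)
        got = inf.compute_elbo(state, ds, cfg)
        want = naive_elbo_gaussian(ds, state, cfg)
        assert got == pytest.approx(want, rel=1e-10)

    def test_all_masked_dataset_is_pure_negative_kl(self):
        data = np.ones((5, 3))
        mask = np.zeros((5, 3), dtype=bool)
        ds = MultiOmicsDataset(
            views=[ViewMatrix(name="v", data=data, mask=mask, likelihood="gaussian")]
        )
        cfg = TrainingConfig(K_initial=2)
        state = initialize_model(ds, cfg, seed=0)
        terms = inf.elbo_terms(state, ds, cfg)
        assert terms["loglik"] == 0.0
        assert sum(terms.values()) <= 0.0

    def test_nonfinite_elbo_names_offending_term(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, cfg = _prepared_state(ds, k=2)
        state.factors.mean[0, 0] = np.inf
        with pytest.raises(FloatingPointError, match="kl_factors|loglik"):
            inf.compute_elbo(state, ds, cfg)


class TestInvariants:
    def test_elbo_monotone_per_coordinate_update(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        cfg = TrainingConfig(K_initial=3, n_restarts=1)
        state = initialize_model(ds, cfg, seed=1)
        prev = inf.compute_elbo(state, ds, cfg)
        for _ in range(15):
            for step in ("w", "z", "theta", "alpha", "tau"):
                if step == "w":
                    state.weights = inf.update_weights(state, ds, True)
                elif step == "z":
                    state.factors = inf.update_factors(state, ds)
                elif step == "theta":
                    state.sparsity = inf.update_sparsity(state, cfg)
                elif step == "alpha":
                    state.ard = inf.update_ard(state, cfg)
                else:
                    for m, v in enumerate(ds.views):
                        state.noise[m] = inf.update_noise(state, ds, cfg, m)
                elbo = inf.compute_elbo(state, ds, cfg)
                assert elbo >= prev - 1e-8 * abs(prev), f"ELBO dropped at {step}"
                prev = elbo

    def test_masked_entries_are_opaque_end_to_end(self, mixed_dataset):
        ds, _ = mixed_dataset
        scrambled = copy.deepcopy(ds)
        rng = np.random.default_rng(0)
        for v in scrambled.views:
            fill = 1.0 if v.likelihood != "gaussian" else 777.0
            v.data = np.where(v.mask, v.data, fill)
        cfg = TrainingConfig(K_initial=3, n_restarts=1, max_iterations=30)
        m1 = train_once(ds, cfg, seed=3)
        m2 = train_once(scrambled, cfg, seed=3)
        assert m1.final_elbo == m2.final_elbo
        np.testing.assert_allclose(m1.state.factors.mean, m2.state.factors.mean,
                                   atol=1e-12)

    def test_scaling_equivariance_gaussian(self, tiny_gaussian):
        # y -> c y with tau and ARD priors scaled by c^2 leaves q(Z) invariant
        ds, _ = tiny_gaussian
        c = 10.0
        scaled = copy.deepcopy(ds)
        for v in scaled.views:
            v.data = v.data * c
        cfg = TrainingConfig(K_initial=2, fix_k=True, n_restarts=1, max_iterations=40)
        cfg2 = cfg.replace(tau_prior=(1e-5, 1e-5 * c**2), ard_prior=(1e-5, 1e-5 * c**2))
        m1 = train_once(ds, cfg, seed=4)
        m2 = train_once(scaled, cfg2, seed=4)
        np.testing.assert_allclose(m1.state.factors.mean, m2.state.factors.mean,
                                   rtol=1e-6, atol=1e-8)

    def test_factor_second_moment_dominates_squared_mean(self, small_trained):
        model, _, _ = small_trained
        fac = model.state.factors
        assert np.all(fac.second_moment >= fac.mean**2 - 1e-12)

    def test_gaussian_pseudodata_is_centred_data_with_tau_precision(self, tiny_gaussian):
        ds, _ = tiny_gaussian
        state, _ = _prepared_state(ds, k=2)
        pg = inf.gaussian_pseudodata(ds.views[0], state.noise[0], state.intercepts[0])
        y, t = gaussian_targets(ds.views[0], state.noise[0].expectation, state.intercepts[0])
        np.testing.assert_allclose(pg.y_tilde, y, atol=1e-12)
        np.testing.assert_allclose(pg.precision, t, atol=1e-12)
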