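"""Mean-field variational updates and the evidence lower bound.

The model, per view m:

    y_nd ~ p(y | x_nd),  x_nd = z_n . w_d (+ mu_d for non-gaussian views)
    z_n ~ N(0, I_K)
    w_dk = s_dk * what_dk,  s_dk ~ Ber(theta_km),  what_dk ~ N(0, 1/alpha_km)
    theta_km ~ Beta(a0, b0),  alpha_km ~ Gamma(a0, b0)
    gaussian views: y_nd ~ N(x_nd, 1/tau_dm), tau_dm ~ Gamma(a0, b0)
    bernoulli:      y_nd ~ Ber(sigma(x_nd))
    poisson:        y_nd ~ Poi(lambda(x_nd)), lambda = softplus

The variational family factorises over samples (full K x K covariance per
sample), over (feature, factor) weight pairs (joint spike-and-slab), and
over all hyper-parameters. Non-gaussian likelihoods are handled through
quadratic bounds (see :mod:`omifa.bounds`) that turn every observed entry
into a gaussian pseudo-observation with a per-entry site precision, so one
set of conjugate updates covers all likelihoods. Every update below is the
exact coordinate-ascent maximiser of the ELBO given the other factors, so
on gaussian data the ELBO is non-decreasing after every single update.

Masked entries are excluded from every sum via the observation mask; the
values stored at masked positions are never read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma, expit, gammaln, xlogy

from . import bounds
from .dataset import MultiOmicsDataset, ViewMatrix
from .state import (
    ARDState,
    BoundAuxiliary,
    FactorPosterior,
    ModelState,
    NoiseState,
    SparsityState,
    TrainingConfig,
    WeightPosterior,
)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ViewPseudoGaussian:
    """Gaussian-equivalent evidence of one view: targets and per-entry precision."""

    y_tilde: np.ndarray    # N x D, intercept-removed, zero at masked entries
    precision: np.ndarray  # N x D, mask * site precision


# ----------------------------------------------------------------- targets

def gaussian_pseudodata(view: ViewMatrix, noise: NoiseState, intercept=None) -> ViewPseudoGaussian:
    """Centred data with E[tau] precision, for a gaussian view."""
    mu = np.zeros(view.n_features) if intercept is None else intercept
    y = np.where(view.mask, view.data - mu[None, :], 0.0)
    prec = view.mask * noise.expectation[None, :]
    return ViewPseudoGaussian(y, prec)


def view_pseudodata(state: ModelState, view: ViewMatrix, m: int) -> ViewPseudoGaussian:
    """Gaussian-equivalent targets of view m under the current state."""
    if view.likelihood == "gaussian":
        return gaussian_pseudodata(view, state.noise[m], state.intercepts[m])
    aux = state.aux[m]
    y = np.where(view.mask, aux.pseudo_data - state.intercepts[m][None, :], 0.0)
    prec = view.mask * aux.site_precision
    return ViewPseudoGaussian(y, prec)


def all_pseudodata(state: ModelState, dataset: MultiOmicsDataset) -> list:
    return [view_pseudodata(state, v, m) for m, v in enumerate(dataset.views)]


# -------------------------------------------------------- predictor moments

def predictor_moments(factors: FactorPosterior, wp: WeightPosterior):
    """Mean and variance of x = z . w per entry (N x D each)."""
    ew = wp.expected_weight
    varw = wp.expected_weight_sq - ew**2
    mean = factors.mean @ ew.T
    # w^T Sigma_n w per (n, d) + sum_k E[z_k^2] Var[w_k]
    quad = np.einsum("dj,njk,dk->nd", ew, factors.cov, ew, optimize=True)
    var = quad + factors.second_moment @ varw.T
    return mean, var


# ----------------------------------------------------------------- updates

def update_factors(state: ModelState, dataset: MultiOmicsDataset) -> FactorPosterior:
    """Exact gaussian update of q(z_n) from all (pseudo-)gaussian evidence.

    A sample with no observed evidence anywhere falls back to the N(0, I)
    prior.
    """
    n, k = state.factors.mean.shape
    prec = np.broadcast_to(np.eye(k), (n, k, k)).copy()
    lin = np.zeros((n, k))
    for m, view in enumerate(dataset.views):
        pg = view_pseudodata(state, view, m)
        wp = state.weights[m]
        ew = wp.expected_weight
        varw = wp.expected_weight_sq - ew**2
        prec += np.einsum("nd,dj,dk->njk", pg.precision, ew, ew, optimize=True)
        diag = pg.precision @ varw  # N x K
        prec[:, np.arange(k), np.arange(k)] += diag
        lin += (pg.precision * pg.y_tilde) @ ew
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    mean = np.einsum("njk,nk->nj", cov, lin)
    return FactorPosterior(mean=mean, cov=cov)


def update_weights(
    state: ModelState,
    dataset: MultiOmicsDataset,
    sparsity_active: bool = True,
) -> list:
    """Joint spike-and-slab update of q(s, w_hat), factor by factor.

    Factors are swept sequentially within each view; the residual seen by
    factor k always uses the freshest expectations of the other factors.
    With ``sparsity_active`` False (burn-in) the inclusion probabilities are
    clamped to 1 and only the slab moments move.
    """
    fac = state.factors
    ezz = fac.cross_moment()       # N x K x K
    ez2 = fac.second_moment        # N x K
    out = []
    for m, view in enumerate(dataset.views):
        pg = view_pseudodata(state, view, m)
        e_alpha = state.ard[m].expectation
        logit_theta = state.sparsity[m].expectation_logit()
        wp = state.weights[m]
        ew = wp.expected_weight.copy()
        gamma = wp.gamma.copy()
        mu1 = wp.mean_given_included.copy()
        var1 = wp.var_given_included.copy()
        oty = pg.precision * pg.y_tilde
        k_tot = state.K_current
        for k in range(k_tot):
            q = pg.precision.T @ ez2[:, k]                  # D
            czk = ezz[:, :, k]                              # N x K
            cross = ((pg.precision.T @ czk) * ew).sum(axis=1)
            h = oty.T @ fac.mean[:, k] - cross + ew[:, k] * q
            lam = e_alpha[k] + q
            mu = h / lam
            if sparsity_active:
                logit = (
                    logit_theta[k]
                    + 0.5 * np.log(e_alpha[k])
                    - 0.5 * np.log(lam)
                    + 0.5 * h * mu
                )
                g = expit(logit)
            else:
                g = np.ones_like(h)
            gamma[:, k] = g
            mu1[:, k] = mu
            var1[:, k] = 1.0 / lam
            ew[:, k] = g * mu
        out.append(
            WeightPosterior(
                gamma=gamma,
                mean_given_included=mu1,
                var_given_included=var1,
                var_spike=1.0 / e_alpha,
            )
        )
    return out


def update_ard(state: ModelState, config: TrainingConfig) -> list:
    """Conjugate Gamma update of q(alpha_km) from expected squared slab weights."""
    a0, b0 = config.ard_prior
    out = []
    for wp in state.weights:
        d = wp.gamma.shape[0]
        shape = np.full(state.K_current, a0 + 0.5 * d)
        rate = b0 + 0.5 * wp.expected_slab_sq.sum(axis=0)
        out.append(ARDState(shape=shape, rate=rate))
    return out


def update_sparsity(state: ModelState, config: TrainingConfig) -> list:
    """Conjugate Beta update of q(theta_km) from summed inclusion probabilities."""
    a0, b0 = config.theta_prior
    out = []
    for wp in state.weights:
        d = wp.gamma.shape[0]
        s = wp.gamma.sum(axis=0)
        out.append(SparsityState(a=a0 + s, b=b0 + d - s))
    return out


def expected_squared_residual(state: ModelState, pg: ViewPseudoGaussian, m: int) -> np.ndarray:
    """E[(y_tilde - z.w)^2] per entry (meaningful at observed entries only)."""
    ex, varx = predictor_moments(state.factors, state.weights[m])
    return pg.y_tilde**2 - 2.0 * pg.y_tilde * ex + ex**2 + varx


def update_noise(state: ModelState, dataset: MultiOmicsDataset, config: TrainingConfig, m: int) -> NoiseState:
    """Conjugate Gamma update of q(tau_dm) from expected squared residuals."""
    view = dataset.views[m]
    if view.likelihood != "gaussian":
        raise ValueError("noise update applies to gaussian views only")
    a0, b0 = config.tau_prior
    pg = gaussian_pseudodata(view, state.noise[m], state.intercepts[m])
    r2 = expected_squared_residual(state, pg, m)
    nobs = view.mask.sum(axis=0)
    shape = a0 + 0.5 * nobs
    rate = b0 + 0.5 * np.where(view.mask, r2, 0.0).sum(axis=0)
    return NoiseState(shape=shape, rate=rate)


def update_bounds(state: ModelState, dataset: MultiOmicsDataset, m: int):
    """Refresh the bound parameters and intercept of a non-gaussian view.

    xi is set to its optimal value (sqrt(E[x^2]) for bernoulli, E[x] for
    poisson), the gaussian-equivalent sites are recomputed, and the offset
    mu_d is re-estimated as the precision-weighted mean of the residual
    pseudo-data over observed samples.
    """
    view = dataset.views[m]
    ex_zw, varx = predictor_moments(state.factors, state.weights[m])
    mu = state.intercepts[m]
    ex = ex_zw + mu[None, :]
    ex2 = ex**2 + varx
    if view.likelihood == "bernoulli":
        xi = np.sqrt(np.maximum(ex2, 0.0))
        pseudo, prec = bounds.bernoulli_sites(view.data, xi)
    elif view.likelihood == "poisson":
        if np.any(view.data[view.mask] > 1e6):
            raise ValueError("poisson counts > 1e6 exceed the bound's numerical range")
        xi = ex
        pseudo, prec = bounds.poisson_sites(view.data, xi)
    else:
        raise ValueError("bound update applies to non-gaussian views only")
    aux = BoundAuxiliary(xi=xi, pseudo_data=pseudo, site_precision=prec)
    wprec = view.mask * prec
    denom = wprec.sum(axis=0)
    resid = np.where(view.mask, pseudo - ex_zw, 0.0)
    new_mu = np.divide(
        (wprec * resid).sum(axis=0),
        denom,
        out=np.zeros_like(mu),
        where=denom > 0,
    )
    return aux, new_mu


# -------------------------------------------------------------------- ELBO

def _gamma_kl(a, b, a0, b0):
    """KL( Gamma(a,b) || Gamma(a0,b0) ), elementwise."""
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def _beta_kl(a, b, a0, b0):
    """KL( Beta(a,b) || Beta(a0,b0) ), elementwise."""
    return (
        betaln(a0, b0)
        - betaln(a, b)
        + (a - a0) * digamma(a)
        + (b - b0) * digamma(b)
        + (a0 - a + b0 - b) * digamma(a + b)
    )


def elbo_terms(state: ModelState, dataset: MultiOmicsDataset, config: TrainingConfig) -> dict:
    """All additive ELBO contributions, by name."""
    terms = {}

    # --- expected data log-likelihood (exact gaussian; bound otherwise)
    ll = 0.0
    for m, view in enumerate(dataset.views):
        ex_zw, varx = predictor_moments(state.factors, state.weights[m])
        if view.likelihood == "gaussian":
            ns = state.noise[m]
            pg = gaussian_pseudodata(view, ns, state.intercepts[m])
            r2 = pg.y_tilde**2 - 2.0 * pg.y_tilde * ex_zw + ex_zw**2 + varx
            per = 0.5 * (ns.expectation_log[None, :] - _LOG2PI) - 0.5 * ns.expectation[None, :] * r2
            ll += per[view.mask].sum()
        else:
            mu = state.intercepts[m]
            ex = ex_zw + mu[None, :]
            ex2 = ex**2 + varx
            xi = state.aux[m].xi
            if view.likelihood == "bernoulli":
                per = bounds.expected_bernoulli_bound(view.data, ex, ex2, xi)
            else:
                per = bounds.expected_poisson_bound(view.data, ex, ex2, xi)
            ll += per[view.mask].sum()
    terms["loglik"] = ll

    # --- factors: -KL( q(Z) || N(0, I) )
    fac = state.factors
    k = state.K_current
    sign, logdet = np.linalg.slogdet(fac.cov)
    tr = np.einsum("nkk->n", fac.cov)
    terms["kl_factors"] = -0.5 * np.sum(tr + (fac.mean**2).sum(axis=1) - k - logdet)

    # --- weights: E[log p(s,what | theta, alpha)] + H[q(s, what)]
    wterm = 0.0
    for m, wp in enumerate(state.weights):
        g = wp.gamma
        eln_t = digamma(state.sparsity[m].a) - digamma(state.sparsity[m].a + state.sparsity[m].b)
        eln_1mt = digamma(state.sparsity[m].b) - digamma(state.sparsity[m].a + state.sparsity[m].b)
        wterm += (g * eln_t[None, :] + (1.0 - g) * eln_1mt[None, :]).sum()
        wterm += -(xlogy(g, g) + xlogy(1.0 - g, 1.0 - g)).sum()
        e_alpha = state.ard[m].expectation
        eln_alpha = state.ard[m].expectation_log
        esq = wp.expected_slab_sq
        d = g.shape[0]
        wterm += (0.5 * (eln_alpha[None, :] - _LOG2PI) - 0.5 * e_alpha[None, :] * esq).sum()
        v1 = np.maximum(wp.var_given_included, 1e-300)
        v0 = np.maximum(wp.var_spike, 1e-300)
        wterm += 0.5 * (g * (np.log(2.0 * np.pi * np.e * v1))).sum()
        wterm += 0.5 * ((1.0 - g) * np.log(2.0 * np.pi * np.e * v0)[None, :]).sum()
    terms["weights"] = wterm

    # --- hyperparameter KLs
    a0t, b0t = config.theta_prior
    a0a, b0a = config.ard_prior
    a0n, b0n = config.tau_prior
    terms["kl_sparsity"] = -sum(_beta_kl(sp.a, sp.b, a0t, b0t).sum() for sp in state.sparsity)
    terms["kl_ard"] = -sum(_gamma_kl(ar.shape, ar.rate, a0a, b0a).sum() for ar in state.ard)
    terms["kl_noise"] = -sum(
        _gamma_kl(ns.shape, ns.rate, a0n, b0n).sum() for ns in state.noise if ns is not None
    )
    return terms


def compute_elbo(state: ModelState, dataset: MultiOmicsDataset, config: TrainingConfig) -> float:
    """Evidence lower bound of the current state; raises if non-finite."""
    terms = elbo_terms(state, dataset, config)
    total = sum(terms.values())
    if not np.isfinite(total):
        bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
        raise FloatingPointError(f"non-finite ELBO; offending terms: {bad}")
    return total
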