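"""Independent naive-loop reference implementations.

Everything here is computed with explicit Python loops straight from the
model equations, deliberately sharing no code with the package internals,
so it can serve as an oracle for the vectorized updates.
"""

import numpy as np
from scipy.special import betaln, digamma, expit, gammaln

LOG2PI = np.log(2.0 * np.pi)


def gaussian_targets(view, e_tau, intercept):
    """Per-entry (target, precision) for a gaussian view, loops only."""
    n, d = view.data.shape
    y = np.zeros((n, d))
    t = np.zeros((n, d))
    for i in range(n):
        for j in range(d):
            if view.mask[i, j]:
                y[i, j] = view.data[i, j] - intercept[j]
                t[i, j] = e_tau[j]
    return y, t


def naive_factor_update(dataset, targets, ew_list, ew2_list):
    """Per-sample gaussian posterior over factors, brute-force sums.

    targets: per-view (y, t) from gaussian_targets; ew/ew2: expectations
    of weights per view.
    """
    n = dataset.n_samples
    k = ew_list[0].shape[1]
    means = np.zeros((n, k))
    covs = np.zeros((n, k, k))
    for i in range(n):
        prec = np.eye(k)
        lin = np.zeros(k)
        for m, view in enumerate(dataset.views):
            y, t = targets[m]
            ew, ew2 = ew_list[m], ew2_list[m]
            for j in range(view.n_features):
                if not view.mask[i, j]:
                    continue
                for a in range(k):
                    lin[a] += t[i, j] * y[i, j] * ew[j, a]
                    for b in range(k):
                        if a == b:
                            prec[a, a] += t[i, j] * ew2[j, a]
                        else:
                            prec[a, b] += t[i, j] * ew[j, a] * ew[j, b]
        cov = np.linalg.inv(prec)
        covs[i] = cov
        means[i] = cov @ lin
    return means, covs


def naive_weight_update(view, y, t, z_mean, z_cov, e_alpha, logit_theta, ew0, sparsity_active=True):
    """Sequential spike-and-slab update for one view, scalar loops.

    ew0 is the starting expected-weight matrix (copied); returns
    (gamma, mu1, var1, ew).
    """
    n, d = view.data.shape
    k = z_mean.shape[1]
    ew = ew0.copy()
    gamma = np.zeros((d, k))
    mu1 = np.zeros((d, k))
    var1 = np.zeros((d, k))
    for kk in range(k):
        for j in range(d):
            q = 0.0
            h = 0.0
            for i in range(n):
                if not view.mask[i, j]:
                    continue
                ez2 = z_mean[i, kk] ** 2 + z_cov[i, kk, kk]
                q += t[i, j] * ez2
                cross = 0.0
                for a in range(k):
                    if a == kk:
                        continue
                    ezz = z_cov[i, a, kk] + z_mean[i, a] * z_mean[i, kk]
                    cross += ezz * ew[j, a]
                h += t[i, j] * (y[i, j] * z_mean[i, kk] - cross)
            lam = e_alpha[kk] + q
            mu = h / lam
            if sparsity_active:
                logit = (
                    logit_theta[kk]
                    + 0.5 * np.log(e_alpha[kk])
                    - 0.5 * np.log(lam)
                    + 0.5 * h * mu
                )
                g = expit(logit)
            else:
                g = 1.0
            gamma[j, kk] = g
            mu1[j, kk] = mu
            var1[j, kk] = 1.0 / lam
            ew[j, kk] = g * mu
    return gamma, mu1, var1, ew


def naive_r2_per_factor(dataset, targets, z_mean, ew_list):
    """R^2 of each single factor in each view, double loops."""
    m_views = len(dataset.views)
    k = z_mean.shape[1]
    out = np.zeros((m_views, k))
    for m, view in enumerate(dataset.views):
        y, _ = targets[m]
        denom = 0.0
        for i in range(view.n_samples):
            for j in range(view.n_features):
                if view.mask[i, j]:
                    denom += y[i, j] ** 2
        for kk in range(k):
            num = 0.0
            for i in range(view.n_samples):
                for j in range(view.n_features):
                    if view.mask[i, j]:
                        num += (y[i, j] - z_mean[i, kk] * ew_list[m][j, kk]) ** 2
            out[m, kk] = 1.0 - num / denom
    return out


def naive_gamma_kl(a, b, a0, b0):
    return (
        (a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b
    )


def naive_beta_kl(a, b, a0, b0):
    return (
        betaln(a0, b0) - betaln(a, b)
        + (a - a0) * digamma(a) + (b - b0) * digamma(b)
        + (a0 - a + b0 - b) * digamma(a + b)
    )


def naive_elbo_gaussian(dataset, state, config):
    """ELBO of an all-gaussian model, summed term by term with loops."""
    total = 0.0
    z_mean = state.factors.mean
    z_cov = state.factors.cov
    n, k = z_mean.shape
    # data term
    for m, view in enumerate(dataset.views):
        e_tau = state.noise[m].shape / state.noise[m].rate
        eln_tau = digamma(state.noise[m].shape) - np.log(state.noise[m].rate)
        wp = state.weights[m]
        ew = wp.gamma * wp.mean_given_included
        ew2 = wp.gamma * (wp.mean_given_included**2 + wp.var_given_included)
        for i in range(n):
            for j in range(view.n_features):
                if not view.mask[i, j]:
                    continue
                y = view.data[i, j] - state.intercepts[m][j]
                ex = 0.0
                ex2 = 0.0
                for a in range(k):
                    ex += z_mean[i, a] * ew[j, a]
                for a in range(k):
                    for b in range(k):
                        ezz = z_cov[i, a, b] + z_mean[i, a] * z_mean[i, b]
                        eww = ew2[j, a] if a == b else ew[j, a] * ew[j, b]
                        ex2 += ezz * eww
                r2 = y * y - 2 * y * ex + ex2
                total += 0.5 * (eln_tau[j] - LOG2PI) - 0.5 * e_tau[j] * r2
    # -KL(q(Z) || N(0,I))
    for i in range(n):
        sign, logdet = np.linalg.slogdet(z_cov[i])
        total -= 0.5 * (np.trace(z_cov[i]) + z_mean[i] @ z_mean[i] - k - logdet)
    # weights + hyperparameters
    for m in range(len(dataset.views)):
        wp = state.weights[m]
        sp = state.sparsity[m]
        ar = state.ard[m]
        e_alpha = ar.shape / ar.rate
        eln_alpha = digamma(ar.shape) - np.log(ar.rate)
        eln_t = digamma(sp.a) - digamma(sp.a + sp.b)
        eln_1mt = digamma(sp.b) - digamma(sp.a + sp.b)
        d = wp.gamma.shape[0]
        for j in range(d):
            for a in range(wp.gamma.shape[1]):
                g = wp.gamma[j, a]
                mu = wp.mean_given_included[j, a]
                v1 = wp.var_given_included[j, a]
                v0 = wp.var_spike[a]
                esq = g * (mu * mu + v1) + (1 - g) * v0
                total += g * eln_t[a] + (1 - g) * eln_1mt[a]
                if 0 < g < 1:
                    total += -(g * np.log(g) + (1 - g) * np.log(1 - g))
                total += 0.5 * (eln_alpha[a] - LOG2PI) - 0.5 * e_alpha[a] * esq
                total += 0.5 * g * np.log(2 * np.pi * np.e * v1)
                total += 0.5 * (1 - g) * np.log(2 * np.pi * np.e * v0)
        a0t, b0t = config.theta_prior
        a0a, b0a = config.ard_prior
        a0n, b0n = config.tau_prior
        for a in range(len(sp.a)):
            total -= naive_beta_kl(sp.a[a], sp.b[a], a0t, b0t)
            total -= naive_gamma_kl(ar.shape[a], ar.rate[a], a0a, b0a)
        ns = state.noise[m]
        for j in range(len(ns.shape)):
            total -= naive_gamma_kl(ns.shape[j], ns.rate[j], a0n, b0n)
    return total


def naive_bh(pvalues):
    """Benjamini-Hochberg adjusted p-values, textbook procedure."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        idx = order[rank_from_end - 1]
        val = min(prev, p[idx] * n / rank_from_end)
        adj[idx] = val
        prev = val
    return adj


def naive_two_sample_t(x, y):
    """Equal-variance two-sample t statistic, textbook formula."""
    nx, ny = len(x), len(y)
    sx = np.var(x, ddof=1)
    sy = np.var(y, ddof=1)
    sp2 = ((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
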