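"""Quadratic variational lower bounds for non-gaussian likelihoods.

Both bounds replace an intractable log-likelihood term log p(y | x), where
x is the linear predictor, by a quadratic function of x that (i) never
exceeds the exact log-likelihood and (ii) touches it at the bound parameter
xi. A quadratic-in-x bound is exactly a gaussian pseudo-observation: each
observed entry contributes an effective precision (``site precision``) and
an effective target (``pseudo-data``), so the conjugate gaussian updates of
the factor model apply unchanged to binary and count views.

* Bernoulli: the Jaakkola-Jordan logistic bound. Tight at xi^2 = x^2; the
  optimal refresh is xi = sqrt(E[x^2]) under the variational posterior.
* Poisson with softplus rate link: a curvature-majorisation (Taylor-type)
  bound. The negative log-likelihood f(x) = lambda(x) - y log lambda(x) has
  globally bounded second derivative f''(x) <= 1/4 + c*y with
  c = sup_x d^2/dx^2 [-log lambda(x)] ~= 0.1671 < 0.17, so expanding around
  xi with curvature 1/4 + 0.17*y gives a valid lower bound, tight at
  xi = x; the optimal refresh is xi = E[x].
"""

import numpy as np
from scipy.special import expit, gammaln

from .links import link_lambda

# global upper bound on the y-coefficient of f''(x); the true supremum is
# ~0.16710 (attained near x = 0.495)
POISSON_CURVATURE = 0.17


# ---------------------------------------------------------------- bernoulli

def jj_lambda(xi):
    """Jaakkola-Jordan curvature function tanh(xi/2)/(4 xi); 1/8 at xi=0."""
    xi = np.abs(np.asarray(xi, dtype=float))
    out = np.full_like(xi, 0.125)
    big = xi > 1e-8
    out[big] = np.tanh(xi[big] / 2.0) / (4.0 * xi[big])
    return out


def bernoulli_loglik(y, x):
    """Exact log p(y|x) = log sigma((2y-1) x)."""
    return -np.logaddexp(0.0, -(2.0 * np.asarray(y) - 1.0) * np.asarray(x))


def bernoulli_bound(y, x, xi):
    """Jaakkola-Jordan lower bound on log p(y|x) at bound parameter xi."""
    xi = np.abs(np.asarray(xi, dtype=float))
    lam = jj_lambda(xi)
    return (
        -np.logaddexp(0.0, -xi)
        + (np.asarray(y) - 0.5) * np.asarray(x)
        - xi / 2.0
        - lam * (np.asarray(x) ** 2 - xi**2)
    )


def bernoulli_sites(y, xi):
    """Gaussian-equivalent (pseudo_data, site_precision) of the JJ bound."""
    prec = 2.0 * jj_lambda(xi)
    pseudo = (np.asarray(y, dtype=float) - 0.5) / prec
    return pseudo, prec


def expected_bernoulli_bound(y, ex, ex2, xi):
    """E_q of the JJ bound given E[x] and E[x^2]."""
    xi = np.abs(np.asarray(xi, dtype=float))
    lam = jj_lambda(xi)
    return (
        -np.logaddexp(0.0, -xi)
        + (np.asarray(y) - 0.5) * ex
        - xi / 2.0
        - lam * (ex2 - xi**2)
    )


# ------------------------------------------------------------------ poisson

def poisson_loglik(y, x):
    """Exact log p(y|x) with rate lambda(x) = log(1+e^x)."""
    y = np.asarray(y, dtype=float)
    rate = np.maximum(link_lambda(x), 1e-300)
    term = np.where(y > 0, y * np.log(rate), 0.0)
    return term - rate - gammaln(y + 1.0)


def poisson_site_precision(y):
    """Curvature majorant 1/4 + 0.17 y, valid for all x."""
    return 0.25 + POISSON_CURVATURE * np.asarray(y, dtype=float)


def _poisson_grad_neg(y, xi):
    """f'(xi) of the negative log-likelihood f = lambda - y log lambda."""
    y = np.asarray(y, dtype=float)
    rate = np.maximum(link_lambda(xi), 1e-300)
    return expit(xi) * (1.0 - y / rate)


def poisson_bound(y, x, xi):
    """Curvature-bound lower bound on log p(y|x), tight at xi = x."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    prec = poisson_site_precision(y)
    return (
        poisson_loglik(y, xi)
        - _poisson_grad_neg(y, xi) * (x - xi)
        - 0.5 * prec * (x - xi) ** 2
    )


def poisson_sites(y, xi):
    """Gaussian-equivalent (pseudo_data, site_precision) around xi."""
    prec = poisson_site_precision(y)
    pseudo = np.asarray(xi, dtype=float) - _poisson_grad_neg(y, xi) / prec
    return pseudo, prec


def expected_poisson_bound(y, ex, ex2, xi):
    """E_q of the Poisson bound given E[x] and E[x^2]."""
    y = np.asarray(y, dtype=float)
    prec = poisson_site_precision(y)
    return (
        poisson_loglik(y, xi)
        - _poisson_grad_neg(y, xi) * (ex - xi)
        - 0.5 * prec * (ex2 - 2.0 * xi * ex + xi**2)
    )
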