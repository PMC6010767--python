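"""Variational posterior state, training configuration and trained-model containers."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FactorPosterior:
    """q(Z): per-sample gaussian with full K x K covariance.

    ``mean`` is N x K; ``cov`` is N x K x K (the factor coupling within a
    sample is kept; samples factorise).
    """

    mean: np.ndarray
    cov: np.ndarray

    @property
    def second_moment(self) -> np.ndarray:
        """Elementwise E[z^2] (N x K)."""
        diag = np.einsum("nkk->nk", self.cov)
        return self.mean**2 + diag

    def cross_moment(self) -> np.ndarray:
        """E[z z^T] per sample (N x K x K)."""
        return self.cov + self.mean[:, :, None] * self.mean[:, None, :]


@dataclass
class WeightPosterior:
    """q(W, S) for one view: spike-and-slab per (feature, factor).

    gamma is the posterior inclusion probability q(s=1); the slab moments
    are conditional on inclusion. ``var_spike`` holds the variance of the
    excluded-branch slab q(w_hat | s=0) = N(0, 1/E[alpha]), one value per
    factor, frozen at the time of the weight update.
    """

    gamma: np.ndarray               # D x K in [0, 1]
    mean_given_included: np.ndarray  # D x K
    var_given_included: np.ndarray   # D x K
    var_spike: np.ndarray            # K

    @property
    def expected_weight(self) -> np.ndarray:
        return self.gamma * self.mean_given_included

    @property
    def expected_weight_sq(self) -> np.ndarray:
        """E[w^2] = gamma * (mu1^2 + var1)  (w = 0 on the spike branch)."""
        return self.gamma * (self.mean_given_included**2 + self.var_given_included)

    @property
    def expected_slab_sq(self) -> np.ndarray:
        """E[w_hat^2] marginal over s (enters the ARD update)."""
        return self.expected_weight_sq + (1.0 - self.gamma) * self.var_spike[None, :]


@dataclass
class ARDState:
    """q(alpha_k) = Gamma(shape_k, rate_k), one per (factor, view)."""

    shape: np.ndarray  # K
    rate: np.ndarray   # K

    @property
    def expectation(self) -> np.ndarray:
        return self.shape / self.rate

    @property
    def expectation_log(self) -> np.ndarray:
        from scipy.special import digamma

        return digamma(self.shape) - np.log(self.rate)


@dataclass
class SparsityState:
    """q(theta_k) = Beta(a_k, b_k), one per (factor, view)."""

    a: np.ndarray  # K
    b: np.ndarray  # K

    @property
    def expectation(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def expectation_logit(self) -> np.ndarray:
        """E[log theta - log(1-theta)]."""
        from scipy.special import digamma

        return digamma(self.a) - digamma(self.b)


@dataclass
class NoiseState:
    """q(tau_d) = Gamma(shape_d, rate_d) for a gaussian view."""

    shape: np.ndarray  # D
    rate: np.ndarray   # D

    @property
    def expectation(self) -> np.ndarray:
        return self.shape / self.rate

    @property
    def expectation_log(self) -> np.ndarray:
        from scipy.special import digamma

        return digamma(self.shape) - np.log(self.rate)


@dataclass
class BoundAuxiliary:
    """Bound parameters and gaussian-equivalent sites for a non-gaussian view."""

    xi: np.ndarray              # N x D, >= 0 for bernoulli
    pseudo_data: np.ndarray     # N x D
    site_precision: np.ndarray  # N x D, > 0


@dataclass
class ModelState:
    """All variational posteriors plus fixed offsets, for one model."""

    factors: FactorPosterior
    weights: list            # WeightPosterior per view
    ard: list                # ARDState per view
    sparsity: list           # SparsityState per view
    noise: list              # NoiseState per gaussian view, else None
    aux: list                # BoundAuxiliary per non-gaussian view, else None
    intercepts: list         # D_m vector per view
    K_current: int


@dataclass
class TrainingConfig:
    """Every knob of the training procedure.

    Defaults follow standard practice for this model class: start from
    K_initial = 25 factors and prune any factor explaining less than 2% of
    the variance in every view. Burn-in runs the first iterations with the
    feature-wise sparsity deactivated (inclusion probabilities clamped to 1)
    to avoid early factor splitting. Prior hyperparameters are proper but
    effectively uninformative.
    """

    K_initial: int = 25
    variance_threshold: float = 0.02
    burn_in_iterations: int = 10
    max_iterations: int = 500
    elbo_rel_tolerance: float = 1e-5
    n_restarts: int = 10
    seed: int = 0
    prune_every: int = 5
    fix_k: bool = False          # if True, never prune (threshold ignored)
    ard_prior: tuple = (1e-5, 1e-5)
    tau_prior: tuple = (1e-5, 1e-5)
    theta_prior: tuple = (1.0, 1.0)

    def __post_init__(self):
        if self.K_initial < 1:
            raise ValueError("K_initial must be >= 1")
        if not (0.0 <= self.variance_threshold < 1.0):
            raise ValueError("variance_threshold must be in [0, 1)")
        if self.max_iterations < 1 or self.prune_every < 1 or self.n_restarts < 1:
            raise ValueError("max_iterations, prune_every, n_restarts must be >= 1")
        if self.burn_in_iterations < 0:
            raise ValueError("burn_in_iterations must be >= 0")
        if self.elbo_rel_tolerance <= 0:
            raise ValueError("elbo_rel_tolerance must be > 0")

    def replace(self, **kw) -> "TrainingConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrainedModel:
    """Frozen posterior expectations plus the training trace."""

    state: ModelState
    elbo_trace: list              # (iteration, elbo)
    pruning_events: list          # (iteration, original factor index)
    config: TrainingConfig
    view_names: list
    likelihoods: list
    sample_names: list
    feature_names: list           # list of per-view feature-name lists
    restart_elbos: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.state.K_current

    @property
    def final_elbo(self) -> float:
        return self.elbo_trace[-1][1]

    @property
    def factors(self) -> np.ndarray:
        """Posterior mean of Z (N x K)."""
        return self.state.factors.mean

    def weight_matrix(self, view) -> np.ndarray:
        """Expected weights E[W] (D x K) of a view, by name or index."""
        m = view if isinstance(view, int) else self.view_names.index(view)
        return self.state.weights[m].expected_weight


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset, for recovery experiments."""

    Z_true: np.ndarray            # N x K_true
    W_true: list                  # D_m x K_true per view
    activity: np.ndarray          # M x K_true bool: factor active in view
    likelihoods: list
    tau_true: list                # per-view D vector (gaussian) or None
    theta: float
    missing_fraction: float
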