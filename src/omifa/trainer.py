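"""Training orchestration: initialization, burn-in, pruning, restarts.

Training is coordinate-ascent variational inference with three procedural
additions on top of the raw updates:

* a *burn-in* period during which the feature-wise sparsity is deactivated
  (inclusion probabilities clamped to 1 and the sparsity-level posterior
  frozen at its prior), which avoids early splitting of factors;
* *factor pruning*: every ``prune_every`` iterations after burn-in, factors
  explaining less than ``variance_threshold`` of the variance in every view
  are removed, so the effective number of factors is learned;
* *random restarts*: the ELBO landscape is non-convex, so ``train`` runs
  several independently seeded fits and keeps the one with the highest
  final ELBO.
"""

from __future__ import annotations

import logging

import numpy as np

from . import inference
from .dataset import MultiOmicsDataset, validate_dataset
from .downstream import per_factor_r2
from .state import (
    ARDState,
    BoundAuxiliary,
    FactorPosterior,
    ModelState,
    NoiseState,
    SparsityState,
    TrainedModel,
    TrainingConfig,
    WeightPosterior,
)

logger = logging.getLogger("omifa")


def initialize_model(dataset: MultiOmicsDataset, config: TrainingConfig, seed=None) -> ModelState:
    """Seeded initial state: random factor means, weights at their prior.

    Gaussian views are centred through a fixed feature-wise intercept (the
    observed feature mean) and their noise precision is initialised at the
    reciprocal empirical feature variance; non-gaussian views start with a
    zero intercept and bound parameters xi = 0 (a valid bound everywhere).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    k = config.K_initial
    a0a, b0a = config.ard_prior
    a0t, b0t = config.theta_prior

    factors = FactorPosterior(
        mean=rng.standard_normal((n, k)),
        cov=np.broadcast_to(np.eye(k), (n, k, k)).copy(),
    )
    weights, ard, sparsity, noise, aux, intercepts = [], [], [], [], [], []
    for view in dataset.views:
        d = view.n_features
        e_alpha0 = a0a / b0a
        weights.append(
            WeightPosterior(
                gamma=np.ones((d, k)),
                mean_given_included=np.zeros((d, k)),
                var_given_included=np.full((d, k), 1.0 / e_alpha0),
                var_spike=np.full(k, 1.0 / e_alpha0),
            )
        )
        ard.append(ARDState(shape=np.full(k, a0a), rate=np.full(k, b0a)))
        sparsity.append(SparsityState(a=np.full(k, a0t), b=np.full(k, b0t)))
        if view.likelihood == "gaussian":
            nobs = view.mask.sum(axis=0)
            mu = np.zeros(d)
            var = np.ones(d)
            for j in np.flatnonzero(nobs > 0):
                col = view.data[view.mask[:, j], j]
                mu[j] = col.mean()
                v = col.var()
                var[j] = v if v > 0 else 1.0
            intercepts.append(mu)
            noise.append(NoiseState(shape=np.ones(d), rate=var))
            aux.append(None)
        else:
            intercepts.append(np.zeros(d))
            noise.append(None)
            xi = np.zeros_like(view.data)
            if view.likelihood == "bernoulli":
                from .bounds import bernoulli_sites

                pseudo, prec = bernoulli_sites(view.data, xi)
            else:
                from .bounds import poisson_sites

                pseudo, prec = poisson_sites(view.data, xi)
            aux.append(BoundAuxiliary(xi=xi, pseudo_data=pseudo, site_precision=prec))
    return ModelState(
        factors=factors,
        weights=weights,
        ard=ard,
        sparsity=sparsity,
        noise=noise,
        aux=aux,
        intercepts=intercepts,
        K_current=k,
    )


def prune_factors(state: ModelState, dataset: MultiOmicsDataset, threshold: float):
    """Drop every factor explaining < threshold variance in *all* views.

    Returns the (possibly shrunk) state and the list of dropped column
    indices (relative to the current state). Pruning to zero factors is
    allowed; callers should treat it as a degenerate outcome.
    """
    if threshold <= 0:
        return state, []
    r2 = per_factor_r2(state, dataset)
    with np.errstate(invalid="ignore"):
        best = np.nanmax(r2, axis=0)
    keep = np.flatnonzero(~(best < threshold))
    dropped = [int(j) for j in np.flatnonzero(best < threshold)]
    if not dropped:
        return state, []
    kkeep = keep
    fac = FactorPosterior(
        mean=state.factors.mean[:, kkeep],
        cov=state.factors.cov[np.ix_(range(state.factors.mean.shape[0]), kkeep, kkeep)],
    )
    weights = [
        WeightPosterior(
            gamma=w.gamma[:, kkeep],
            mean_given_included=w.mean_given_included[:, kkeep],
            var_given_included=w.var_given_included[:, kkeep],
            var_spike=w.var_spike[kkeep],
        )
        for w in state.weights
    ]
    ard = [ARDState(shape=a.shape[kkeep], rate=a.rate[kkeep]) for a in state.ard]
    sparsity = [SparsityState(a=s.a[kkeep], b=s.b[kkeep]) for s in state.sparsity]
    new = ModelState(
        factors=fac,
        weights=weights,
        ard=ard,
        sparsity=sparsity,
        noise=state.noise,
        aux=state.aux,
        intercepts=state.intercepts,
        K_current=len(kkeep),
    )
    return new, dropped


def _iterate(state: ModelState, dataset: MultiOmicsDataset, config: TrainingConfig, sparsity_active: bool):
    """One full sweep of coordinate updates, in a fixed order."""
    state.weights = inference.update_weights(state, dataset, sparsity_active)
    state.factors = inference.update_factors(state, dataset)
    if sparsity_active:
        state.sparsity = inference.update_sparsity(state, config)
    state.ard = inference.update_ard(state, config)
    for m, view in enumerate(dataset.views):
        if view.likelihood == "gaussian":
            state.noise[m] = inference.update_noise(state, dataset, config, m)
    for m, view in enumerate(dataset.views):
        if view.likelihood != "gaussian":
            state.aux[m], state.intercepts[m] = inference.update_bounds(state, dataset, m)
    return state


def train_once(dataset: MultiOmicsDataset, config: TrainingConfig, seed=None) -> TrainedModel:
    """One fit: burn-in, coordinate updates, pruning, convergence on the ELBO."""
    validate_dataset(dataset)
    state = initialize_model(dataset, config, seed=seed)
    orig = list(range(config.K_initial))
    trace, events = [], []
    elbo_prev = None
    for it in range(1, config.max_iterations + 1):
        sparsity_active = it > config.burn_in_iterations
        state = _iterate(state, dataset, config, sparsity_active)
        elbo = inference.compute_elbo(state, dataset, config)
        trace.append((it, elbo))
        prune_checked = False
        pruned_this = False
        if (not config.fix_k) and sparsity_active and it % config.prune_every == 0:
            prune_checked = True
            state, dropped = prune_factors(state, dataset, config.variance_threshold)
            if dropped:
                pruned_this = True
                for j in sorted(dropped, reverse=True):
                    events.append((it, orig[j]))
                    del orig[j]
                logger.info("iter %d: pruned %d factor(s), K=%d", it, len(dropped), state.K_current)
            if state.K_current == 0:
                logger.warning("all factors pruned at iteration %d", it)
                break
        converged = (
            elbo_prev is not None
            and sparsity_active
            and (config.fix_k or (prune_checked and not pruned_this))
            and abs(elbo - elbo_prev) < config.elbo_rel_tolerance * abs(elbo)
        )
        elbo_prev = None if pruned_this else elbo
        logger.debug("iter %d: elbo=%.6f K=%d", it, elbo, state.K_current)
        if converged:
            break
    return TrainedModel(
        state=state,
        elbo_trace=trace,
        pruning_events=events,
        config=config,
        view_names=[v.name for v in dataset.views],
        likelihoods=[v.likelihood for v in dataset.views],
        sample_names=list(dataset.sample_names),
        feature_names=[list(v.feature_names) for v in dataset.views],
    )


def restart_seeds(config: TrainingConfig):
    """Deterministic per-restart seeds derived from the master seed."""
    return [(config.seed + 7919 * i) % (2**31 - 1) for i in range(config.n_restarts)]


def train(dataset: MultiOmicsDataset, config: TrainingConfig = None) -> TrainedModel:
    """Multi-restart training; returns the restart with the highest final ELBO.

    Ties are broken in favour of the lowest restart index.
    """
    if config is None:
        config = TrainingConfig()
    models = [train_once(dataset, config, seed=s) for s in restart_seeds(config)]
    finals = [m.final_elbo for m in models]
    best = int(np.argmax(finals))  # argmax returns the first maximum: lowest index wins ties
    chosen = models[best]
    chosen.restart_elbos = finals
    return chosen
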