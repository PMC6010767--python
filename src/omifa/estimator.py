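"""Scikit-learn-style estimator front end.

:class:`MOFA` wraps the variational trainer as a decomposition estimator:
``fit`` learns factors and sparse view-specific weights, ``transform``
returns (or projects new samples onto) the latent factor space, and the
fitted attributes expose the trained posterior expectations. The functional
interface in :mod:`omifa.trainer` remains available; this class is the
recommended entry point and composes with sklearn model-selection tooling
through ``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import inference
from .dataset import MultiOmicsDataset, ViewMatrix
from .downstream import variance_explained
from .state import FactorPosterior, TrainingConfig
from .trainer import train, train_once


def as_dataset(X, likelihoods=None, view_names=None, sample_names=None) -> MultiOmicsDataset:
    """Coerce input to a :class:`MultiOmicsDataset`.

    Accepts an existing dataset, a single matrix, or a list of matrices /
    DataFrames (NaN = missing). DataFrames contribute sample and feature
    names; plain arrays get positional labels.
    """
    if isinstance(X, MultiOmicsDataset):
        return X
    if isinstance(X, (np.ndarray, pd.DataFrame)):
        X = [X]
    views = []
    n_views = len(X)
    likelihoods = likelihoods or ["gaussian"] * n_views
    for m, xm in enumerate(X):
        name = view_names[m] if view_names else f"view_{m}"
        if isinstance(xm, pd.DataFrame):
            feats = [str(c) for c in xm.columns]
            if sample_names is None:
                sample_names = [str(i) for i in xm.index]
            arr = xm.to_numpy(dtype=float)
        else:
            arr = np.asarray(xm, dtype=float)
            feats = [f"{name}_f{j}" for j in range(arr.shape[1])]
        mask = np.isfinite(arr)
        views.append(
            ViewMatrix(
                name=name,
                data=np.where(mask, arr, 0.0),
                mask=mask,
                likelihood=likelihoods[m],
                feature_names=feats,
            )
        )
    return MultiOmicsDataset(views=views, sample_names=list(sample_names or []))


class MOFA(BaseEstimator):
    """Multi-omics factor analysis: sparse Bayesian group factor model.

    Decomposes M views (samples x features matrices sharing a sample axis)
    into a common factor matrix Z and view-specific sparse weights W^m,
    Y^m ~ Z W^m^T + noise, trained by mean-field variational inference.
    Factor-and-view-wise ARD priors plus feature-wise spike-and-slab priors
    let the model switch factors off per view and learn the number of
    factors by pruning.

    Parameters
    ----------
    n_factors : int, default 25
        Initial number of factors (upper bound when pruning is active).
    variance_threshold : float, default 0.02
        A factor is pruned when it explains less than this fraction of
        variance in every view. Ignored when ``fix_n_factors``.
    fix_n_factors : bool, default False
        Keep exactly ``n_factors`` factors (no pruning).
    likelihoods : list of str, optional
        Per-view observation model (gaussian | bernoulli | poisson) when
        fitting raw matrices; ignored if a MultiOmicsDataset is passed.
    burn_in : int, default 10
        Iterations with feature-wise sparsity deactivated.
    max_iter : int, default 500
    tol : float, default 1e-5
        Relative ELBO change declaring convergence (checked at pruning
        checkpoints).
    n_restarts : int, default 10
        Independently seeded fits; the highest-ELBO model is kept.
    prune_every : int, default 5
    random_state : int, default 0

    Attributes
    ----------
    model_ : TrainedModel
        Full posterior expectations and training trace.
    factors_ : ndarray (n_samples, n_factors_)
        Posterior mean of Z.
    weights_ : list of ndarray (n_features_m, n_factors_)
        Expected weights per view.
    n_factors_ : int
        Retained factors after pruning.
    elbo_ : float
    variance_explained_ : DataFrame
        R-squared per (view, factor) plus the all-factor column.
    """

    def __init__(
        self,
        n_factors: int = 25,
        variance_threshold: float = 0.02,
        fix_n_factors: bool = False,
        likelihoods=None,
        burn_in: int = 10,
        max_iter: int = 500,
        tol: float = 1e-5,
        n_restarts: int = 10,
        prune_every: int = 5,
        random_state: int = 0,
    ):
        self.n_factors = n_factors
        self.variance_threshold = variance_threshold
        self.fix_n_factors = fix_n_factors
        self.likelihoods = likelihoods
        self.burn_in = burn_in
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.prune_every = prune_every
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            K_initial=self.n_factors,
            variance_threshold=self.variance_threshold,
            fix_k=self.fix_n_factors,
            burn_in_iterations=self.burn_in,
            max_iterations=self.max_iter,
            elbo_rel_tolerance=self.tol,
            n_restarts=self.n_restarts,
            prune_every=self.prune_every,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        dataset = as_dataset(X, likelihoods=self.likelihoods)
        config = self._config()
        if config.n_restarts == 1:
            model = train_once(dataset, config)
        else:
            model = train(dataset, config)
        self.model_ = model
        self.dataset_ = dataset
        self.factors_ = model.factors
        self.weights_ = [w.expected_weight for w in model.state.weights]
        self.n_factors_ = model.n_factors
        self.elbo_ = model.final_elbo
        self.elbo_trace_ = list(model.elbo_trace)
        self.view_names_ = list(model.view_names)
        self.variance_explained_ = variance_explained(model, dataset).to_frame()
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).factors_

    def transform(self, X=None, n_iter: int = 20):
        """Factor values: the training set's, or a projection of new data.

        New samples are projected by running factor (and, for non-gaussian
        views, bound) updates with the trained weights, noise and
        intercepts held fixed.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the model first")
        if X is None:
            return self.factors_
        dataset = as_dataset(X, likelihoods=self.likelihoods)
        state = self.model_.state
        import copy

        proj = copy.deepcopy(state)
        n = dataset.n_samples
        k = proj.K_current
        proj.factors = FactorPosterior(
            mean=np.zeros((n, k)), cov=np.broadcast_to(np.eye(k), (n, k, k)).copy()
        )
        for m, view in enumerate(dataset.views):
            if view.likelihood != "gaussian":
                from .bounds import bernoulli_sites, poisson_sites

                xi = np.zeros_like(view.data)
                sites = (
                    bernoulli_sites(view.data, xi)
                    if view.likelihood == "bernoulli"
                    else poisson_sites(view.data, xi)
                )
                from .state import BoundAuxiliary

                proj.aux[m] = BoundAuxiliary(xi=xi, pseudo_data=sites[0], site_precision=sites[1])
        for _ in range(n_iter):
            proj.factors = inference.update_factors(proj, dataset)
            for m, view in enumerate(dataset.views):
                if view.likelihood != "gaussian":
                    proj.aux[m], _ = inference.update_bounds(proj, dataset, m)
        return proj.factors.mean
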