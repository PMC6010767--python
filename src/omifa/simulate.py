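"""Synthetic data from the model's own generative process.

The simulator draws factors Z ~ N(0, 1), per-view weights as the product of
a Bernoulli inclusion indicator (probability ``theta``) and a normal slab
whose precision encodes view-wise factor activity: alpha = 1 for a factor
active in a view, alpha = 1e3 for an inactive one (near-zero weights).
Gaussian views add N(0, 1/tau) noise; bernoulli views sample
Ber(sigma(z.w)); poisson views sample Poi(softplus(z.w)). Missingness is
applied either to random values or to whole sample-rows of a view
(assay-level missingness). Everything is reproducible from the seed.

``standard_scenarios`` registers the simulation designs used for model
validation, mixed-likelihood model comparison, view-activity-pattern
recovery and imputation benchmarking, each with a desk-scale variant
(reduced feature count) for quick runs.
"""

from __future__ import annotations

import numpy as np

from .dataset import MultiOmicsDataset, ViewMatrix
from .links import link_lambda, link_sigma
from .state import SimulationTruth

ALPHA_ACTIVE = 1.0
ALPHA_INACTIVE = 1e3


def simulate_dataset(
    n_views: int = 3,
    n_samples: int = 100,
    n_features=1000,
    k_true: int = 10,
    activity=None,
    likelihoods=None,
    theta: float = 0.5,
    tau: float = 1.0,
    missing_fraction: float = 0.0,
    missing_mode: str = "values",
    missing_view=None,
    seed: int = 0,
):
    """Draw one dataset plus its ground truth.

    Parameters
    ----------
    n_features : int or sequence of int
        Features per view.
    activity : None, "random", or (M x K) boolean array
        Which factor is active in which view. None = all active. "random"
        samples each cell Ber(0.5) but guarantees every factor at least one
        active view.
    likelihoods : sequence of str, optional
        Defaults to all-gaussian.
    theta : float
        Inclusion probability of a weight given an active factor.
    tau : float
        Gaussian noise precision.
    missing_mode : {"values", "assays"}
        Random single entries, or whole sample-rows of one view
        (``missing_view``, default: all views independently).
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(n_features):
        n_features = [int(n_features)] * n_views
    if len(n_features) != n_views:
        raise ValueError("n_features must have one entry per view")
    if likelihoods is None:
        likelihoods = ["gaussian"] * n_views
    if len(likelihoods) != n_views:
        raise ValueError("likelihoods must have one entry per view")
    for lik in likelihoods:
        if lik not in ("gaussian", "bernoulli", "poisson"):
            raise ValueError(f"invalid likelihood tag {lik!r}")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    if missing_mode not in ("values", "assays"):
        raise ValueError("missing_mode must be 'values' or 'assays'")

    if activity is None:
        act = np.ones((n_views, k_true), dtype=bool)
    elif isinstance(activity, str) and activity == "random":
        act = rng.random((n_views, k_true)) < 0.5
        for k in np.flatnonzero(~act.any(axis=0)):
            act[rng.integers(n_views), k] = True
    else:
        act = np.asarray(activity, dtype=bool)
        if act.shape != (n_views, k_true):
            raise ValueError(f"activity pattern must have shape ({n_views}, {k_true})")

    z = rng.standard_normal((n_samples, k_true))
    views, w_true, tau_true = [], [], []
    for m in range(n_views):
        d = n_features[m]
        alpha = np.where(act[m], ALPHA_ACTIVE, ALPHA_INACTIVE)
        what = rng.standard_normal((d, k_true)) / np.sqrt(alpha)[None, :]
        s = rng.random((d, k_true)) < theta
        w = s * what
        x = z @ w.T
        lik = likelihoods[m]
        if lik == "gaussian":
            data = x + rng.standard_normal((n_samples, d)) / np.sqrt(tau)
            tau_true.append(np.full(d, tau))
        elif lik == "bernoulli":
            data = (rng.random((n_samples, d)) < link_sigma(x)).astype(float)
            tau_true.append(None)
        else:
            data = rng.poisson(link_lambda(x)).astype(float)
            tau_true.append(None)
        mask = np.ones((n_samples, d), dtype=bool)
        if missing_fraction > 0:
            if missing_mode == "values":
                mask = rng.random((n_samples, d)) >= missing_fraction
            else:
                if missing_view is None or missing_view == m:
                    rows = rng.random(n_samples) < missing_fraction
                    mask[rows, :] = False
        views.append(
            ViewMatrix(
                name=f"view_{m}",
                data=data,
                mask=mask,
                likelihood=lik,
                feature_names=[f"view_{m}_f{j}" for j in range(d)],
            )
        )
        w_true.append(w)
    dataset = MultiOmicsDataset(
        views=views, sample_names=[f"sample_{i}" for i in range(n_samples)]
    )
    truth = SimulationTruth(
        Z_true=z,
        W_true=w_true,
        activity=act,
        likelihoods=list(likelihoods),
        tau_true=tau_true,
        theta=theta,
        missing_fraction=missing_fraction,
    )
    return dataset, truth


def standard_scenarios() -> dict:
    """Named simulation presets; ``<name>_desk`` variants shrink D only.

    * ``model_validation``: 3 gaussian views, N=100, K_true=10, complete.
    * ``model_comparison``: one view per likelihood (gaussian, bernoulli,
      poisson), N=100, D=5000/view, K_true=10, 5% values missing at random.
    * ``activity_patterns`` / ``activity_patterns_k15``: gaussian-only,
      no missing values, random view-activity pattern, K_true 10 / 15.
    * ``imputation``: 2 gaussian views for masking experiments.
    """
    reg = {
        "model_validation": dict(
            n_views=3, n_samples=100, n_features=1000, k_true=10,
            likelihoods=["gaussian"] * 3, missing_fraction=0.0,
        ),
        "model_comparison": dict(
            n_views=3, n_samples=100, n_features=5000, k_true=10,
            likelihoods=["gaussian", "bernoulli", "poisson"],
            missing_fraction=0.05, missing_mode="values",
        ),
        "activity_patterns": dict(
            n_views=3, n_samples=100, n_features=5000, k_true=10,
            likelihoods=["gaussian"] * 3, activity="random", missing_fraction=0.0,
        ),
        "activity_patterns_k15": dict(
            n_views=3, n_samples=100, n_features=5000, k_true=15,
            likelihoods=["gaussian"] * 3, activity="random", missing_fraction=0.0,
        ),
        "imputation": dict(
            n_views=2, n_samples=100, n_features=500, k_true=10,
            likelihoods=["gaussian"] * 2, missing_fraction=0.0,
        ),
    }
    desk_d = {
        "model_validation": 200,
        "model_comparison": 500,
        "activity_patterns": 300,
        "activity_patterns_k15": 300,
        "imputation": 150,
    }
    for name, d in desk_d.items():
        params = dict(reg[name])
        params["n_features"] = d
        reg[name + "_desk"] = params
    return reg


def simulate_scenario(name: str, seed: int = 0, **overrides):
    """Instantiate a named preset (overrides win over preset values)."""
    reg = standard_scenarios()
    if name not in reg:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(reg)}")
    params = dict(reg[name])
    params.update(overrides)
    return simulate_dataset(seed=seed, **params)
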