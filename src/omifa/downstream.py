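"""Interpretation of a trained model.

Variance decomposition per factor and view, loading scaling and top
features, feature-set enrichment on the weights, and imputation of missing
entries (including whole missing assays) from the model equation.

All downstream computations use posterior expectations. For bernoulli and
poisson views the variance decomposition is computed on the gaussian
pseudo-data scale produced by the likelihood bounds, since raw R-squared is
not meaningful for non-gaussian observations; imputation instead maps the
linear predictor through the appropriate link (probability scale for
bernoulli, rate scale for poisson).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import MultiOmicsDataset
from .inference import view_pseudodata
from .links import link_lambda, link_sigma
from .state import ModelState, TrainedModel


@dataclass
class VarianceDecomposition:
    """R-squared per (view, factor) and per view with all factors jointly."""

    per_factor: np.ndarray     # M x K
    per_view_total: np.ndarray  # M
    view_names: list
    undefined_views: list       # views with zero centred sum of squares

    def to_frame(self) -> pd.DataFrame:
        k = self.per_factor.shape[1]
        df = pd.DataFrame(
            self.per_factor,
            index=self.view_names,
            columns=[f"factor_{i + 1}" for i in range(k)],
        )
        df["all_factors"] = self.per_view_total
        return df


def per_factor_r2(state: ModelState, dataset: MultiOmicsDataset) -> np.ndarray:
    """Fraction of variance explained by each single factor in each view.

    R2_{m,k} = 1 - sum_obs (y - z_k w_k - mu)^2 / sum_obs (y - mu)^2,
    evaluated with posterior means over observed entries; pseudo-data scale
    for non-gaussian views.
    """
    k = state.K_current
    out = np.zeros((len(dataset.views), k))
    z = state.factors.mean
    for m, view in enumerate(dataset.views):
        pg = view_pseudodata(state, view, m)
        mask = view.mask
        denom = (pg.y_tilde[mask] ** 2).sum()
        if denom == 0:
            out[m, :] = np.nan
            continue
        ew = state.weights[m].expected_weight
        for j in range(k):
            resid = pg.y_tilde - np.outer(z[:, j], ew[:, j])
            out[m, j] = 1.0 - (resid[mask] ** 2).sum() / denom
    return out


def variance_explained(model_or_state, dataset: MultiOmicsDataset) -> VarianceDecomposition:
    """Variance decomposition of a trained model over a dataset."""
    state = model_or_state.state if isinstance(model_or_state, TrainedModel) else model_or_state
    per_factor = per_factor_r2(state, dataset)
    totals = np.zeros(len(dataset.views))
    undefined = []
    z = state.factors.mean
    for m, view in enumerate(dataset.views):
        pg = view_pseudodata(state, view, m)
        mask = view.mask
        denom = (pg.y_tilde[mask] ** 2).sum()
        if denom == 0:
            totals[m] = np.nan
            undefined.append(view.name)
            continue
        resid = pg.y_tilde - z @ state.weights[m].expected_weight.T
        totals[m] = 1.0 - (resid[mask] ** 2).sum() / denom
    return VarianceDecomposition(
        per_factor=per_factor,
        per_view_total=totals,
        view_names=[v.name for v in dataset.views],
        undefined_views=undefined,
    )


# ----------------------------------------------------------------- weights

def scale_loadings(model: TrainedModel, view, factor: int, mode: str = "maxabs") -> np.ndarray:
    """Loadings of one factor scaled for cross-view comparability.

    ``maxabs`` divides by the maximum absolute weight (range [-1, 1]);
    ``l2`` divides by the Euclidean norm. An all-zero vector is returned
    unchanged with a warning.
    """
    w = np.asarray(model.weight_matrix(view))[:, factor].copy()
    if mode == "maxabs":
        s = np.max(np.abs(w))
    elif mode == "l2":
        s = float(np.linalg.norm(w))
    else:
        raise ValueError("mode must be 'maxabs' or 'l2'")
    if s == 0:
        warnings.warn(f"factor {factor} has all-zero weights in view {view!r}; not scaled")
        return w
    return w / s


def top_features(model: TrainedModel, view, factor: int, n: int = 10) -> pd.DataFrame:
    """Features ranked by |expected weight| on one factor.

    Ties are broken by feature label so the ranking is deterministic.
    """
    m = view if isinstance(view, int) else model.view_names.index(view)
    w = model.state.weights[m].expected_weight[:, factor]
    names = np.asarray(model.feature_names[m])
    scaled = scale_loadings(model, m, factor) if np.any(w) else w
    order = sorted(range(len(w)), key=lambda j: (-abs(w[j]), names[j]))[: min(n, len(w))]
    return pd.DataFrame(
        {
            "feature": names[order],
            "weight": w[order],
            "scaled_weight": np.asarray(scaled)[order],
        }
    )


# -------------------------------------------------------------- enrichment

@dataclass
class FeatureSetCollection:
    """Named feature sets (e.g. gene sets read from a GMT file)."""

    sets: dict  # name -> list of feature labels

    def matched(self, feature_names) -> dict:
        """Per set: labels present among ``feature_names`` (order kept)."""
        pool = set(feature_names)
        return {name: [f for f in labels if f in pool] for name, labels in self.sets.items()}


def enrichment(
    model: TrainedModel,
    view,
    sets: FeatureSetCollection,
    factor: int,
    fdr: float = 0.01,
    use_absolute: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Feature-set enrichment of one factor's weights.

    For each set, a parametric two-sample t-test compares the mean weight of
    the foreground (features in the set) against the background (all other
    features of the view); p-values are Benjamini-Hochberg adjusted across
    sets within the factor. Sets with fewer than 2 matched features are
    skipped with a reason.
    """
    m = view if isinstance(view, int) else model.view_names.index(view)
    w = model.state.weights[m].expected_weight[:, factor]
    if use_absolute:
        w = np.abs(w)
    names = list(model.feature_names[m])
    index = {f: j for j, f in enumerate(names)}
    rows, skipped = [], []
    for set_name, labels in sets.sets.items():
        idx = [index[f] for f in labels if f in index]
        unmatched = len(labels) - len(idx)
        if len(idx) < 2 or len(w) - len(idx) < 2:
            skipped.append((set_name, f"{len(idx)} matched features (need >= 2 in both groups)"))
            continue
        fg = w[idx]
        bg = np.delete(w, idx)
        t, p = stats.ttest_ind(fg, bg, equal_var=True, alternative=alternative)
        rows.append((set_name, len(labels), len(idx), unmatched, t, p))
    df = pd.DataFrame(
        rows, columns=["set", "set_size", "matched_size", "unmatched", "t", "p_value"]
    )
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] <= fdr
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    df.attrs["skipped"] = skipped
    return df


# -------------------------------------------------------------- imputation

def predict_views(model: TrainedModel) -> list:
    """Model predictions per view on the observation scale.

    Gaussian: E[Z] E[W]^T + mu; bernoulli: sigma(.) (probability scale);
    poisson: softplus(.) (rate scale).
    """
    z = model.state.factors.mean
    preds = []
    for m, lik in enumerate(model.likelihoods):
        x = z @ model.state.weights[m].expected_weight.T + model.state.intercepts[m][None, :]
        if lik == "gaussian":
            preds.append(x)
        elif lik == "bernoulli":
            preds.append(link_sigma(x))
        else:
            preds.append(link_lambda(x))
    return preds


def impute(model: TrainedModel, dataset: MultiOmicsDataset) -> MultiOmicsDataset:
    """Fill every missing entry from the model equation; observed entries untouched."""
    preds = predict_views(model)
    completed = copy.deepcopy(dataset)
    for m, view in enumerate(completed.views):
        view.data = np.where(view.mask, view.data, preds[m])
    return completed


def _knn_impute(data: np.ndarray, mask: np.ndarray, k: int = 5) -> np.ndarray:
    """k-nearest-neighbour baseline: sample-space neighbours, euclidean
    distance on the observed intersection of features."""
    from sklearn.impute import KNNImputer

    x = np.where(mask, data, np.nan)
    return KNNImputer(n_neighbors=k).fit_transform(x)


def imputation_experiment(
    dataset: MultiOmicsDataset,
    mode: str = "values",
    fraction: float = 0.1,
    k_fixed: int = 10,
    n_repetitions: int = 15,
    seed: int = 0,
    target_view: int = 0,
    config=None,
) -> pd.DataFrame:
    """Masking experiment: hide data, refit, impute, score against truth.

    In each repetition either a random ``fraction`` of the observed values
    (mode ``"values"``) or all measurements of a random ``fraction`` of the
    samples (mode ``"assays"``) of the target view are masked; the model is
    refit with a fixed number of factors ``k_fixed`` and the masked cells
    are imputed from the model equation. Mean squared error on the masked
    cells is reported next to feature-wise-mean and kNN baselines, with the
    across-repetition mean and standard error in ``DataFrame.attrs["summary"]``.
    """
    from .state import TrainingConfig
    from .trainer import train_once

    if fraction <= 0:
        raise ValueError("fraction must be > 0 (nothing to evaluate otherwise)")
    if mode not in ("values", "assays"):
        raise ValueError("mode must be 'values' or 'assays'")
    if config is None:
        config = TrainingConfig()
    config = config.replace(K_initial=k_fixed, fix_k=True)
    view = dataset.views[target_view]
    rows = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + rep)
        masked = copy.deepcopy(dataset)
        tv = masked.views[target_view]
        if mode == "values":
            hide = (rng.random(tv.data.shape) < fraction) & tv.mask
        else:
            rows_hide = rng.random(tv.n_samples) < fraction
            hide = np.zeros_like(tv.mask)
            hide[rows_hide, :] = tv.mask[rows_hide, :]
        if not hide.any():
            continue
        tv.mask = tv.mask & ~hide
        model = train_once(masked, config, seed=seed + rep)
        truth = view.data[hide]
        pred = predict_views(model)[target_view][hide]
        col_mean = np.array(
            [
                tv.data[tv.mask[:, j], j].mean() if tv.mask[:, j].any() else 0.0
                for j in range(tv.n_features)
            ]
        )
        mean_pred = np.broadcast_to(col_mean, tv.data.shape)[hide]
        knn_pred = _knn_impute(tv.data, tv.mask)[hide]
        rows.append(
            {
                "repetition": rep,
                "n_masked": int(hide.sum()),
                "mse_model": float(np.mean((pred - truth) ** 2)),
                "mse_mean": float(np.mean((mean_pred - truth) ** 2)),
                "mse_knn": float(np.mean((knn_pred - truth) ** 2)),
            }
        )
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("mse_model", "mse_mean", "mse_knn"):
        vals = df[col].to_numpy()
        summary[col] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))))
    df.attrs["summary"] = summary
    return df
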