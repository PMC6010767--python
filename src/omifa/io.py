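"""File formats and model serialization.

Views are delimited text matrices (TSV/CSV) with a header row of feature
names and a first column of sample names; samples are aligned across views
by name (union semantics: a sample absent from a view becomes an
all-missing row). Trained models round-trip through a versioned HDF5
container. Feature sets are read from GMT files.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .dataset import MultiOmicsDataset, ViewMatrix
from .downstream import FeatureSetCollection
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

FORMAT_VERSION = 1


# ------------------------------------------------------------------- views

def read_view_table(path, transpose: bool = False) -> pd.DataFrame:
    """One delimited matrix; empty cells and NA become NaN (masked)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "NaN", ""])
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_views(paths, likelihoods, names=None, transpose=False) -> MultiOmicsDataset:
    """Read and align several view matrices into one dataset.

    ``transpose`` may be a single flag or one per path (True = file stores
    features in rows). Sample alignment is by name over the union of all
    sample labels, in order of first appearance.
    """
    n_views = len(paths)
    if np.isscalar(transpose):
        transpose = [bool(transpose)] * n_views
    if names is None:
        names = [f"view_{m}" for m in range(n_views)]
    frames = [read_view_table(p, t) for p, t in zip(paths, transpose)]
    samples: list = []
    seen = set()
    for df in frames:
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample name {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")
        for s in df.index:
            if s not in seen:
                seen.add(s)
                samples.append(s)
    views = []
    for m, df in enumerate(frames):
        full = df.reindex(samples)
        arr = full.to_numpy(dtype=float)
        mask = np.isfinite(arr)
        views.append(
            ViewMatrix(
                name=names[m],
                data=np.where(mask, arr, 0.0),
                mask=mask,
                likelihood=likelihoods[m],
                feature_names=[str(c) for c in df.columns],
            )
        )
    return MultiOmicsDataset(views=views, sample_names=samples)


def write_view(view: ViewMatrix, sample_names, path):
    """Write one view as TSV with NA at masked positions."""
    arr = np.where(view.mask, view.data, np.nan)
    pd.DataFrame(arr, index=sample_names, columns=view.feature_names).to_csv(
        path, sep="\t", na_rep="NA"
    )


def write_dataset(dataset: MultiOmicsDataset, directory):
    """One TSV per view, named after the view."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for v in dataset.views:
        p = os.path.join(directory, f"{v.name}.tsv")
        write_view(v, dataset.sample_names, p)
        paths.append(p)
    return paths


# --------------------------------------------------------------------- GMT

def read_gmt(path) -> FeatureSetCollection:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    return FeatureSetCollection(sets=sets)


# ------------------------------------------------------------------- model

def _write_str_list(group, name, values):
    group.create_dataset(name, data=np.array([str(v) for v in values], dtype="S"))


def _read_str_list(group, name):
    return [s.decode() for s in group[name][()]]


def save_model(model: TrainedModel, path):
    """Serialize a trained model to a versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config"] = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(model.config).items()
            }
        )
        f.attrs["n_factors"] = model.n_factors
        _write_str_list(f, "sample_names", model.sample_names)
        _write_str_list(f, "view_names", model.view_names)
        _write_str_list(f, "likelihoods", model.likelihoods)
        f.create_dataset("elbo_trace", data=np.array(model.elbo_trace, dtype=float))
        f.create_dataset(
            "pruning_events",
            data=np.array(model.pruning_events, dtype=float).reshape(-1, 2),
        )
        f.create_dataset("restart_elbos", data=np.array(model.restart_elbos, dtype=float))
        fac = f.create_group("factors")
        fac.create_dataset("mean", data=model.state.factors.mean)
        fac.create_dataset("cov", data=model.state.factors.cov)
        for m, name in enumerate(model.view_names):
            g = f.create_group(f"views/{name}")
            _write_str_list(g, "feature_names", model.feature_names[m])
            w = model.state.weights[m]
            g.create_dataset("gamma", data=w.gamma)
            g.create_dataset("mean_given_included", data=w.mean_given_included)
            g.create_dataset("var_given_included", data=w.var_given_included)
            g.create_dataset("var_spike", data=w.var_spike)
            g.create_dataset("ard_shape", data=model.state.ard[m].shape)
            g.create_dataset("ard_rate", data=model.state.ard[m].rate)
            g.create_dataset("theta_a", data=model.state.sparsity[m].a)
            g.create_dataset("theta_b", data=model.state.sparsity[m].b)
            g.create_dataset("intercept", data=model.state.intercepts[m])
            if model.state.noise[m] is not None:
                g.create_dataset("tau_shape", data=model.state.noise[m].shape)
                g.create_dataset("tau_rate", data=model.state.noise[m].rate)
            if model.state.aux[m] is not None:
                g.create_dataset("xi", data=model.state.aux[m].xi)
                g.create_dataset("pseudo_data", data=model.state.aux[m].pseudo_data)
                g.create_dataset("site_precision", data=model.state.aux[m].site_precision)


def load_model(path) -> TrainedModel:
    """Load a model container written by :func:`save_model`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version > FORMAT_VERSION:
            raise ValueError(
                f"model file has format version {version}; this build reads <= {FORMAT_VERSION}"
            )
        raw = json.loads(f.attrs["config"])
        for key in ("ard_prior", "tau_prior", "theta_prior"):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = TrainingConfig(**raw)
        sample_names = _read_str_list(f, "sample_names")
        view_names = _read_str_list(f, "view_names")
        likelihoods = _read_str_list(f, "likelihoods")
        elbo_trace = [(int(i), float(e)) for i, e in f["elbo_trace"][()]]
        pruning_events = [(int(i), int(j)) for i, j in f["pruning_events"][()]]
        restart_elbos = [float(e) for e in f["restart_elbos"][()]]
        factors = FactorPosterior(mean=f["factors/mean"][()], cov=f["factors/cov"][()])
        weights, ard, sparsity, noise, aux, intercepts, feature_names = (
            [], [], [], [], [], [], [],
        )
        for name, lik in zip(view_names, likelihoods):
            g = f[f"views/{name}"]
            feature_names.append(_read_str_list(g, "feature_names"))
            weights.append(
                WeightPosterior(
                    gamma=g["gamma"][()],
                    mean_given_included=g["mean_given_included"][()],
                    var_given_included=g["var_given_included"][()],
                    var_spike=g["var_spike"][()],
                )
            )
            ard.append(ARDState(shape=g["ard_shape"][()], rate=g["ard_rate"][()]))
            sparsity.append(SparsityState(a=g["theta_a"][()], b=g["theta_b"][()]))
            intercepts.append(g["intercept"][()])
            noise.append(
                NoiseState(shape=g["tau_shape"][()], rate=g["tau_rate"][()])
                if "tau_shape" in g
                else None
            )
            aux.append(
                BoundAuxiliary(
                    xi=g["xi"][()],
                    pseudo_data=g["pseudo_data"][()],
                    site_precision=g["site_precision"][()],
                )
                if "xi" in g
                else None
            )
        state = ModelState(
            factors=factors,
            weights=weights,
            ard=ard,
            sparsity=sparsity,
            noise=noise,
            aux=aux,
            intercepts=intercepts,
            K_current=int(f.attrs["n_factors"]),
        )
        return TrainedModel(
            state=state,
            elbo_trace=elbo_trace,
            pruning_events=pruning_events,
            config=config,
            view_names=view_names,
            likelihoods=likelihoods,
            sample_names=sample_names,
            feature_names=feature_names,
            restart_elbos=restart_elbos,
        )


# ------------------------------------------------------------------ tables

def write_trace(model: TrainedModel, path):
    """Tidy training log: iteration, elbo, pruned-this-iteration count."""
    pruned_at = {}
    for it, _ in model.pruning_events:
        pruned_at[it] = pruned_at.get(it, 0) + 1
    rows = [
        {"iteration": it, "elbo": e, "n_pruned": pruned_at.get(it, 0)}
        for it, e in model.elbo_trace
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_factors(model: TrainedModel, path):
    """Samples x factors table of posterior factor values."""
    k = model.n_factors
    pd.DataFrame(
        model.factors,
        index=model.sample_names,
        columns=[f"factor_{i + 1}" for i in range(k)],
    ).to_csv(path, sep="\t")
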