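"""Aligned multi-view dataset containers.

A *view* is one assay: a samples x features matrix with its own observation
likelihood (gaussian for continuous data, bernoulli for binary data, poisson
for counts).  All views share the same ordered sample axis; a sample that was
never assayed in a view is kept as an all-missing row so the latent factors
remain defined for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LIKELIHOODS = ("gaussian", "bernoulli", "poisson")


@dataclass
class ViewMatrix:
    """One assay: an N x D data matrix with a boolean observation mask.

    Parameters
    ----------
    name : str
        Label of the view (e.g. ``"mRNA"``).
    data : ndarray of shape (n_samples, n_features)
        Measurements. Values at masked (unobserved) positions are never read.
    mask : ndarray of bool, shape (n_samples, n_features)
        True where the entry is observed.
    likelihood : {"gaussian", "bernoulli", "poisson"}
        Observation model for this view.
    feature_names : list of str
        One label per column.
    """

    name: str
    data: np.ndarray
    mask: np.ndarray
    likelihood: str
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"view {self.name!r}: data must be 2-D")
        if self.mask.shape != self.data.shape:
            raise ValueError(
                f"view {self.name!r}: mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        if self.likelihood not in LIKELIHOODS:
            raise ValueError(
                f"view {self.name!r}: unknown likelihood {self.likelihood!r}; "
                f"expected one of {LIKELIHOODS}"
            )
        if not self.feature_names:
            self.feature_names = [f"{self.name}_f{j}" for j in range(self.data.shape[1])]
        if len(self.feature_names) != self.data.shape[1]:
            raise ValueError(f"view {self.name!r}: feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def observed_values(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class MultiOmicsDataset:
    """Ordered collection of views sharing one sample axis."""

    views: list
    sample_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.views:
            raise ValueError("dataset needs at least one view")
        n = self.views[0].n_samples
        if not self.sample_names:
            self.sample_names = [f"sample_{i}" for i in range(n)]
        if len(self.sample_names) != n:
            raise ValueError("sample_names length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.views[0].n_samples

    @property
    def n_views(self) -> int:
        return len(self.views)

    def view_names(self) -> list:
        return [v.name for v in self.views]

    def __getitem__(self, name: str) -> ViewMatrix:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class Diagnostic:
    level: str  # "warning" | "error"
    view: str
    message: str


def validate_dataset(dataset: MultiOmicsDataset) -> list:
    """Check structural and domain consistency of a dataset.

    Returns a list of :class:`Diagnostic` warnings (all-missing features,
    constant features, samples unobserved everywhere noted per view).
    Raises ``ValueError`` on fatal problems: row-count mismatches across
    views, non-binary values in a bernoulli view, negative or non-integer
    values in a poisson view.
    """
    diags: list = []
    n = dataset.n_samples
    for v in dataset.views:
        if v.n_samples != n:
            raise ValueError(
                f"view {v.name!r} has {v.n_samples} rows, expected {n} (sample axes must align)"
            )
        obs = v.data[v.mask]
        if v.likelihood == "bernoulli":
            if obs.size and not np.all(np.isin(obs, (0.0, 1.0))):
                bad = obs[~np.isin(obs, (0.0, 1.0))][0]
                raise ValueError(
                    f"bernoulli view {v.name!r} contains non-binary value {bad!r} at an observed cell"
                )
        elif v.likelihood == "poisson":
            if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
                raise ValueError(
                    f"poisson view {v.name!r} contains negative or non-integer observed values"
                )
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError(f"view {v.name!r} has non-finite observed values")
        col_counts = v.mask.sum(axis=0)
        for j in np.flatnonzero(col_counts == 0):
            diags.append(
                Diagnostic("warning", v.name, f"feature {v.feature_names[j]!r} is entirely missing")
            )
        # constant feature: zero variance among >=2 observed values
        for j in np.flatnonzero(col_counts >= 2):
            col = v.data[v.mask[:, j], j]
            if np.ptp(col) == 0:
                diags.append(
                    Diagnostic("warning", v.name, f"feature {v.feature_names[j]!r} is constant")
                )
    observed_any = np.zeros(n, dtype=bool)
    for v in dataset.views:
        observed_any |= v.mask.any(axis=1)
    for i in np.flatnonzero(~observed_any):
        diags.append(
            Diagnostic("warning", "*", f"sample {dataset.sample_names[i]!r} observed in no view")
        )
    return diags
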