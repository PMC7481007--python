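"""Cross-temporal and subspace-projected population decoding.

A linear-discriminant classifier with pooled within-class covariance is
trained at each time bin of the trial on pseudo-population activity and
tested at every other bin, producing a train-time x test-time accuracy grid
whose block structure diagnoses code stability and code morphing.  Before
classification the data are either PCA-denoised at the training bin
(full-space decoding) or projected onto a fixed information subspace
(subspace decoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

from .datasets import (
    EpochWindows,
    DEFAULT_EPOCHS,
    PopulationDataset,
    PseudoPopulation,
    sample_pseudotrial_indices,
)
from .unmixing import Subspace

__all__ = [
    "DecodingGrid",
    "PooledCovLDA",
    "pca_denoise",
    "cross_temporal_decode",
    "decode_distractor",
    "decode_error_trials",
]


class PooledCovLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with pooled covariance and a ridge term.

    The discriminant for class k is the Gaussian-equal-covariance rule
    delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k with S the
    pooled within-class covariance plus ``ridge * trace(S)/d`` on the
    diagonal (the paper-scale regime of a few hundred dimensions and a few
    hundred samples per class is near-singular without it).
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 classes with >= 2 samples each")
        n, d = X.shape
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros((d, d))
        for c in self.classes_:
            resid = X[y == c] - X[y == c].mean(axis=0)
            pooled += resid.T @ resid
        pooled /= n - len(self.classes_)
        if self.ridge:
            pooled = pooled + (self.ridge * np.trace(pooled) / d) * np.eye(d)
        try:
            chol = np.linalg.cholesky(pooled)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular; increase the ridge parameter"
            ) from err
        self._solve = lambda B: np.linalg.solve(
            chol.T, np.linalg.solve(chol, B)
        )
        self.priors_ = counts / n
        self.coef_ = self._solve(self.means_.T).T  # (k, d)
        self.intercept_ = (
            -0.5 * np.einsum("kd,kd->k", self.means_, self.coef_)
            + np.log(self.priors_)
        )
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def pca_denoise(
    train: np.ndarray, test: np.ndarray, var_threshold: float = 0.95
) -> tuple[np.ndarray, np.ndarray, int]:
    """Reconstruct both splits from the train split's top principal components.

    Components are fit on ``train`` only (samples x features); the minimal
    number whose cumulative explained variance reaches ``var_threshold`` is
    kept and both matrices are reconstructed in the original space.
    """
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training samples for PCA")
    pca = PCA(n_components=min(train.shape)).fit(train)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cumvar, var_threshold - 1e-12) + 1)
    n_components = min(n_components, len(cumvar))
    comps = pca.components_[:n_components]
    mean = pca.mean_
    rec_train = (train - mean) @ comps.T @ comps + mean
    rec_test = (test - mean) @ comps.T @ comps + mean
    return rec_train, rec_test, n_components


@dataclass
class DecodingGrid:
    """Train-time x test-time classification accuracy in percent."""

    accuracy: np.ndarray  # (n_bins, n_bins), mean over repeats
    times: np.ndarray  # bin centers, ms
    n_classes: int
    per_repeat: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0)))

    @property
    def chance(self) -> float:
        return 100.0 / self.n_classes

    def _window_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.times >= window[0]) & (self.times < window[1])

    def block_mean(
        self,
        train_window: tuple[float, float],
        test_window: tuple[float, float] | None = None,
    ) -> float:
        """Mean accuracy over grid cells with train (and test) bins in a window."""
        tr = self._window_mask(train_window)
        te = self._window_mask(test_window or train_window)
        if not tr.any() or not te.any():
            raise ValueError("window contains no time bins")
        return float(self.accuracy[np.ix_(tr, te)].mean())

    def diagonal_mean(self, window: tuple[float, float]) -> float:
        mask = self._window_mask(window)
        return float(np.diag(self.accuracy)[mask].mean())


def _rebin(data: PopulationDataset, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate counts to bin_ms resolution -> (rates, bin centers)."""
    factor = bin_ms / data.bin_width
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("bin_ms must be an integer multiple of the data bin width")
    factor = int(round(factor))
    n_bins = data.n_bins // factor
    counts = data.counts[:, :, : n_bins * factor].reshape(
        data.n_trials, data.n_neurons, n_bins, factor
    ).sum(axis=3)
    rates = counts / bin_ms * 1000.0
    centers = data.t_start + bin_ms * (np.arange(n_bins) + 0.5)
    return rates, centers


def cross_temporal_decode(
    data: PopulationDataset,
    projection: Subspace | None = None,
    labels: str = "target",
    bin_ms: float = 100.0,
    n_per_condition: int = 50,
    n_repeats: int = 5,
    var_threshold: float = 0.95,
    ridge: float = 1e-6,
    seed: int | np.random.Generator = 0,
    epochs: EpochWindows = DEFAULT_EPOCHS,
) -> DecodingGrid:
    """Train a decoder at each time bin and test it at every bin.

    Per repeat, a fresh pseudo-population (disjoint train/test trial pools
    per neuron) is sampled; activity is baseline-subtracted per neuron.  If
    ``projection`` is None the training bin's data are PCA-denoised (both
    splits reconstructed with the train bin's components); otherwise both
    splits are projected onto the subspace basis.  Accuracies are averaged
    over repeats.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates, centers = _rebin(data, bin_ms)
    base = data.baseline_rate(epochs["fixation"])
    rates = rates - base[None, :, None]
    n_bins = centers.size
    if n_bins == 0:
        raise ValueError("empty time-bin grid")
    n_classes = len(np.unique(
        data.trials[f"{labels}_location"].to_numpy()[data.correct_mask()]
    ))
    per_repeat = np.empty((n_repeats, n_bins, n_bins))
    for rep in range(n_repeats):
        train_idx, test_idx, pseudo_labels = sample_pseudotrial_indices(
            data, n_per_condition, rng, group_by=labels
        )
        rows = np.arange(data.n_neurons)[:, None]
        # (bins, pseudo-trials, neurons)
        train_act = np.transpose(rates[train_idx, rows, :], (2, 1, 0))
        test_act = np.transpose(rates[test_idx, rows, :], (2, 1, 0))
        if projection is not None:
            train_act = train_act @ projection.basis
            test_act = test_act @ projection.basis
        for i in range(n_bins):
            x_train = train_act[i]
            if projection is None:
                pca = PCA(n_components=min(x_train.shape)).fit(x_train)
                cumvar = np.cumsum(pca.explained_variance_ratio_)
                k = int(np.searchsorted(cumvar, var_threshold - 1e-12) + 1)
                comps = pca.components_[: min(k, len(cumvar))]
                mean = pca.mean_
                x_train_d = (x_train - mean) @ comps.T
                clf = PooledCovLDA(ridge=ridge).fit(x_train_d, pseudo_labels)
                test_d = (test_act - mean) @ comps.T
                for j in range(n_bins):
                    per_repeat[rep, i, j] = clf.score(test_d[j], pseudo_labels)
            else:
                clf = PooledCovLDA(ridge=ridge).fit(x_train, pseudo_labels)
                for j in range(n_bins):
                    per_repeat[rep, i, j] = clf.score(test_act[j], pseudo_labels)
    per_repeat *= 100.0
    return DecodingGrid(
        accuracy=per_repeat.mean(axis=0),
        times=centers,
        n_classes=n_classes,
        per_repeat=per_repeat,
    )


def decode_distractor(
    data: PopulationDataset,
    projection: Subspace | None = None,
    **kwargs,
) -> DecodingGrid:
    """Cross-temporal decoding with trials grouped by distractor location."""
    return cross_temporal_decode(data, projection=projection, labels="distractor", **kwargs)


def decode_error_trials(
    correct_train: np.ndarray,
    correct_train_labels: np.ndarray,
    error_trials: np.ndarray,
    error_labels: np.ndarray,
    projection: Subspace | None = None,
    ridge: float = 1e-6,
) -> float:
    """Accuracy (%) on error trials of a decoder fit on correct trials.

    Inputs are neurons x pseudo-trials matrices (e.g. unmixed activity);
    both are projected onto ``projection`` before classification when given.
    """
    x_train = np.asarray(correct_train, float).T
    x_err = np.asarray(error_trials, float).T
    if projection is not None:
        x_train = x_train @ projection.basis
        x_err = x_err @ projection.basis
    clf = PooledCovLDA(ridge=ridge).fit(x_train, correct_train_labels)
    return 100.0 * clf.score(x_err, error_labels)
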