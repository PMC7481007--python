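"""Subspace comparison and state-space cluster geometry.

Principal angles (with random-subspace nulls), inter-to-intra cluster
distance ratios, per-neuron loading weights and exclusivity, projection
magnitude time courses, effective dimensionality, variance explained,
null-space construction, and element/tuning correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .datasets import ConditionMatrix, EpochWindows, DEFAULT_EPOCHS, PopulationDataset, condition_matrix
from .unmixing import Subspace, build_subspace

__all__ = [
    "PrincipalAngleResult",
    "ClusterMetrics",
    "LoadingWeights",
    "principal_angles",
    "random_subspace_null",
    "inter_intra_ratio",
    "loading_weights",
    "axis_clustering_test",
    "projection_magnitude_timecourse",
    "effective_dimensionality",
    "variance_explained",
    "null_space_projection",
    "element_correlation",
    "per_cell_tuning_correlation",
]


@dataclass
class PrincipalAngleResult:
    """Canonical angles between two subspaces, ascending, in degrees."""

    angles: np.ndarray
    null_distributions: np.ndarray | None = None  # (n_samples, n_angles)

    def significant(self, percentile: float = 5.0) -> np.ndarray:
        """Per-angle flag: observed below the null's percentile (closer than chance)."""
        if self.null_distributions is None:
            raise ValueError("no null distributions attached")
        thresh = np.percentile(self.null_distributions, percentile, axis=0)
        return self.angles < thresh


def _basis(x) -> np.ndarray:
    b = x.basis if isinstance(x, Subspace) else np.asarray(x, float)
    gram = b.T @ b
    if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-8):
        raise ValueError("input columns must form an orthonormal basis")
    return b


def principal_angles(x, y) -> PrincipalAngleResult:
    """Angles from the SVD of X'Y: acos of singular values, ascending, degrees.

    Singular values are clamped to [-1, 1] to absorb floating-point
    overshoot.
    """
    bx, by = _basis(x), _basis(y)
    if bx.shape[0] != by.shape[0]:
        raise ValueError("subspaces live in different ambient dimensions")
    s = np.linalg.svd(bx.T @ by, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))
    return PrincipalAngleResult(angles=np.sort(angles))


def random_subspace_null(
    ambient_dim: int,
    fixed,
    d_random: int,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Principal-angle null: ``fixed`` vs n random ``d_random``-dim subspaces.

    Random subspaces are orthonormalized standard-Gaussian matrices.
    Returns an (n, min(d_fixed, d_random)) array; an observed angle below the
    5th percentile of its per-rank column is significantly closer than
    chance.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    b_fixed = _basis(fixed)
    if d_random > ambient_dim:
        raise ValueError("d_random cannot exceed the ambient dimension")
    n_angles = min(b_fixed.shape[1], d_random)
    out = np.empty((n, n_angles))
    for i in range(n):
        g = rng.standard_normal((ambient_dim, d_random))
        q, _ = np.linalg.qr(g)
        s = np.linalg.svd(b_fixed.T @ q, compute_uv=False)
        out[i] = np.sort(np.degrees(np.arccos(np.clip(s, -1.0, 1.0))))
    return out


@dataclass
class ClusterMetrics:
    """Inter/intra cluster distances with a bootstrap ratio distribution."""

    inter: float
    intra: float
    ratio: float
    boot_ratios: np.ndarray = field(default_factory=lambda: np.empty(0))

    def percentile_interval(self, lo: float = 5.0, hi: float = 95.0) -> tuple[float, float]:
        return (
            float(np.nanpercentile(self.boot_ratios, lo)),
            float(np.nanpercentile(self.boot_ratios, hi)),
        )


def _inter_intra(points: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> tuple[float, float]:
    means = np.stack([points[labels == c].mean(axis=0) for c in classes])
    inter = float(pdist(means).mean()) if len(classes) > 1 else 0.0
    intras = []
    for c in classes:
        cluster = points[labels == c]
        if len(cluster) < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 points; intra undefined")
        intras.append(pdist(cluster).mean())
    return inter, float(np.mean(intras))


def inter_intra_ratio(
    points: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    n_per_cluster: int = 250,
    seed: int | np.random.Generator = 0,
) -> ClusterMetrics:
    """Signal-to-noise geometry of condition clusters in state space.

    inter = grand mean of pairwise Euclidean distances between cluster
    means; intra = grand mean over clusters of the mean pairwise
    within-cluster distance.  The ratio's sampling distribution comes from
    ``n_boot`` bootstrap resamples of ``n_per_cluster`` points per cluster.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 clusters")
    inter, intra = _inter_intra(points, labels, classes)
    if intra == 0:
        raise ValueError("intra-cluster distance is zero; ratio undefined")
    boot = np.empty(n_boot)
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    for bnum in range(n_boot):
        sel = np.concatenate([
            rng.choice(idx, n_per_cluster, replace=True) for idx in idx_by_class
        ])
        lab = np.repeat(classes, n_per_cluster)
        bi, bw = _inter_intra(points[sel], lab, classes)
        # a resample can duplicate every point of a tiny cluster; drop it
        boot[bnum] = bi / bw if bw > 0 else np.nan
    return ClusterMetrics(inter=inter, intra=intra, ratio=inter / intra, boot_ratios=boot)


@dataclass
class LoadingWeights:
    """Per-neuron projection magnitudes into two subspaces."""

    memory: np.ndarray
    preparation: np.ndarray
    correlation: float
    shuffle_null: np.ndarray
    exclusive_memory: np.ndarray  # boolean flags
    exclusive_preparation: np.ndarray

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log2(self.memory / self.preparation)

    @property
    def angle_deg(self) -> np.ndarray:
        """Weight-pair angle atan2(memory, preparation) in [0, 90] degrees."""
        return np.degrees(np.arctan2(self.memory, self.preparation))

    def correlation_significant(self, percentile: float = 95.0) -> bool:
        return self.correlation > np.percentile(self.shuffle_null, percentile)


def loading_weights(
    memory, preparation, n_shuffles: int = 1000, seed: int | np.random.Generator = 0
) -> LoadingWeights:
    """Per-neuron loading weight in each subspace, with exclusivity flags.

    The weight of neuron i in a subspace is the norm of the projection of its
    standard basis vector, i.e. the Euclidean norm of row i of the
    orthonormal basis.  Exclusive neurons are those whose log weight ratio
    deviates more than two SDs from the population mean.  The across-neuron
    weight correlation is tested against ``n_shuffles`` random permutations
    of one subspace's weights.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bm, bp = _basis(memory), _basis(preparation)
    if bm.shape[0] != bp.shape[0]:
        raise ValueError("subspaces must share the ambient dimension")
    w_mem = np.linalg.norm(bm, axis=1)
    w_prep = np.linalg.norm(bp, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(w_mem, w_prep)[0, 1])
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            null[i] = np.corrcoef(rng.permutation(w_mem), w_prep)[0, 1]
        log_ratio = np.log2(np.where(w_prep > 0, w_mem / np.maximum(w_prep, 1e-300), np.inf))
    finite = np.isfinite(log_ratio)
    if finite.any():
        mu, sd = log_ratio[finite].mean(), log_ratio[finite].std()
    else:
        mu, sd = 0.0, 0.0
    with np.errstate(invalid="ignore"):
        z = (log_ratio - mu) / sd if sd > 0 else np.where(np.isinf(log_ratio), log_ratio, 0.0)
    return LoadingWeights(
        memory=w_mem,
        preparation=w_prep,
        correlation=r,
        shuffle_null=null,
        exclusive_memory=z > 2.0,
        exclusive_preparation=z < -2.0,
    )


def axis_clustering_test(
    weights: LoadingWeights,
    n_boot: int = 1000,
    exclusion: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> dict[str, tuple[float, float]]:
    """Bootstrap test for clustering of weight pairs along the axes.

    Per bootstrap a random ``exclusion`` fraction of neurons is dropped and
    the fraction of remaining neurons whose weight-pair angle lies above the
    67.5 degree line or below the 22.5 degree line (near-axis) is computed.
    Returns 5th-95th percentile intervals of the near-axis and off-axis
    fractions.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    angles = weights.angle_deg
    n = angles.size
    if n < 10:
        raise ValueError("need at least 10 neurons")
    n_keep = max(1, int(round(n * (1.0 - exclusion))))
    near = np.empty(n_boot)
    for i in range(n_boot):
        keep = rng.choice(n, n_keep, replace=False)
        a = angles[keep]
        near[i] = np.mean((a > 67.5) | (a < 22.5))
    lo, hi = np.percentile(near, [5, 95])
    return {
        "near_axis": (float(lo), float(hi)),
        "off_axis": (float(1 - hi), float(1 - lo)),
    }


def projection_magnitude_timecourse(
    data: PopulationDataset,
    subspace: Subspace,
    bin_ms: float = 100.0,
    epochs: EpochWindows = DEFAULT_EPOCHS,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Frobenius magnitude of per-bin condition-mean activity in a subspace.

    For each time bin the trial-averaged, baseline-subtracted neurons x
    conditions matrix is projected onto the subspace; the magnitude trace is
    normalized to a maximum of 1 when ``normalize`` is set.  Returns
    ``(times, magnitudes)``.
    """
    from .decoding import _rebin

    rates, centers = _rebin(data, bin_ms)
    base = data.baseline_rate(epochs["fixation"])
    rates = rates - base[None, :, None]
    labels = data.trials["target_location"].to_numpy()
    mask = data.correct_mask()
    classes = np.unique(labels[mask])
    mags = np.empty(centers.size)
    for t in range(centers.size):
        cond = np.stack(
            [rates[mask & (labels == c), :, t].mean(axis=0) for c in classes], axis=1
        )
        mags[t] = np.linalg.norm(subspace.basis.T @ cond)
    if normalize and mags.max() > 0:
        mags = mags / mags.max()
    return centers, mags


def effective_dimensionality(projected: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest number of PCs whose cumulative variance reaches ``threshold``.

    ``projected`` is samples x dims (e.g. single trials projected into a
    subspace).
    """
    projected = np.asarray(projected, float)
    pca = PCA(n_components=min(projected.shape)).fit(projected)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cumvar, threshold - 1e-12) + 1)


def variance_explained(trials: np.ndarray, subspace: Subspace) -> float:
    """Fraction of total (mean-centered) variance captured by a subspace.

    ``trials`` is samples x neurons.
    """
    x = np.asarray(trials, float)
    x = x - x.mean(axis=0)
    total = float(np.sum(x**2))
    if total == 0:
        raise ValueError("zero total variance")
    proj = x @ subspace.basis
    return float(np.sum(proj**2) / total)


def null_space_projection(subspaces: list) -> Subspace:
    """Orthonormal basis of the orthogonal complement of a union of subspaces."""
    bases = np.hstack([_basis(s) for s in subspaces])
    n = bases.shape[0]
    u, s, _ = np.linalg.svd(bases, full_matrices=True)
    rank = int(np.sum(s > 1e-10 * (s[0] if s.size else 1.0)))
    if rank >= n:
        raise ValueError("union of subspaces spans the full space; complement empty")
    return Subspace(basis=u[:, rank:], label="null")


def element_correlation(e1, e2) -> tuple[float, float]:
    """Pearson correlation (r, p) of two flattened condition matrices."""
    v1 = e1.values if isinstance(e1, ConditionMatrix) else np.asarray(e1, float)
    v2 = e2.values if isinstance(e2, ConditionMatrix) else np.asarray(e2, float)
    if v1.shape != v2.shape:
        raise ValueError("elements must have equal shapes")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(v1.ravel(), v2.ravel())
    return float(r), float(p)


def per_cell_tuning_correlation(
    e_a,
    e_b,
    selective_cells: np.ndarray,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Fraction of cells whose tuning correlates across two unmixed elements.

    For each selective cell, the Pearson correlation between its condition
    tuning (rows of the two elements) is tested at ``alpha``; the chance band
    is the 5th-95th percentile of the fraction obtained after shuffling which
    cell's tuning is paired with which (cross-cell tuning shuffle).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    va = (e_a.values if isinstance(e_a, ConditionMatrix) else np.asarray(e_a, float))
    vb = (e_b.values if isinstance(e_b, ConditionMatrix) else np.asarray(e_b, float))
    if va.shape[1] < 3:
        raise ValueError("need at least 3 conditions for per-cell correlation")
    cells = np.asarray(selective_cells)
    va, vb = va[cells], vb[cells]

    def fraction(rows_b: np.ndarray) -> float:
        sig = 0
        for i in range(va.shape[0]):
            if np.ptp(va[i]) == 0 or np.ptp(rows_b[i]) == 0:
                continue
            _, p = sps.pearsonr(va[i], rows_b[i])
            sig += p < alpha
        return sig / va.shape[0]

    observed = fraction(vb)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = fraction(vb[rng.permutation(va.shape[0])])
    lo, hi = np.percentile(null, [5, 95])
    return {
        "fraction_significant": observed,
        "chance_band": (float(lo), float(hi)),
        "null": null,
        "above_chance": observed > hi,
    }
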