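"""Minimally dependent subspace unmixing by mutual-information minimization.

Delay-period population activity is modelled as a 2 x 2 mixture of two
latent activity patterns: a working-memory element M and a motor-preparation
element P,

    D1 = M + a P,        D2 = b M + P,

where D1 and D2 are neurons x conditions condition matrices for the two
delays, and the scalars (a, b) are mixing coefficients (a is the fraction of
preparation activity already present in Delay 1; b is the fraction of memory
activity persisting into Delay 2).  The coefficients are estimated by
minimizing the histogram mutual information between the flattened unmixed
elements; the orthonormal bases of the recovered M and P define the
working-memory and motor-preparation subspaces.

The histogram MI surface is piecewise constant in (a, b), so the optimizer
combines a coarse grid scan with many Nelder-Mead restarts from random
initial points (1,000 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .datasets import ConditionMatrix, PseudoPopulation

__all__ = [
    "MixingSolution",
    "Subspace",
    "MutualInfoUnmixer",
    "sturges_bins",
    "mutual_information",
    "unmix_pair",
    "fit_mixing",
    "build_subspace",
    "unmix_single_trials",
    "unmix_error_trials",
    "unmix_presaccade",
    "unmix_uncorrelated",
    "gram_schmidt_subspaces",
]

_SINGULAR_TOL = 0.05  # exclusion band around the singular curve a*b = 1
_PENALTY = 1e6


def sturges_bins(n: int) -> int:
    """Histogram bin count by Sturges' rule: ceil(1 + log2 n)."""
    if n < 1:
        raise ValueError("sample count must be >= 1")
    return int(np.ceil(1.0 + np.log2(n))) if n > 1 else 1


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int | None = None,
    binning: str = "width",
) -> float:
    """Histogram mutual information between two paired samples, in bits.

    Each array is discretized into ``n_bins`` bins (Sturges' rule on the
    sample count by default) over its own min-max range ("width" binning) or
    into equal-count quantile bins ("frequency").  Joint probabilities come
    from the 2-d histogram; empty cells contribute nothing.  A constant
    array has zero range and, by convention, zero mutual information.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length arrays with >= 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if n_bins is None:
        n_bins = sturges_bins(x.size)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input array: mutual information defined as 0")
        return 0.0
    if binning == "width":
        edges_x = np.linspace(x.min(), x.max(), n_bins + 1)
        edges_y = np.linspace(y.min(), y.max(), n_bins + 1)
    elif binning == "frequency":
        qs = np.linspace(0, 1, n_bins + 1)
        edges_x = np.unique(np.quantile(x, qs))
        edges_y = np.unique(np.quantile(y, qs))
    else:
        raise ValueError(f"unknown binning {binning!r}")
    joint, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ConditionMatrix) else np.asarray(m, float)


def unmix_pair(d1, d2, a: float, b: float):
    """Invert the 2x2 mixing model: M = (D1 - a D2)/(1 - ab), P = (D2 - b D1)/(1 - ab)."""
    v1, v2 = _values(d1), _values(d2)
    if v1.shape != v2.shape:
        raise ValueError("D1 and D2 must have matching shapes")
    det = 1.0 - a * b
    if det == 0:
        raise ValueError(f"singular mixing: a*b = 1 for a={a}, b={b}")
    m = (v1 - a * v2) / det
    p = (v2 - b * v1) / det
    if isinstance(d1, ConditionMatrix):
        m = ConditionMatrix(m, d1.condition_labels, epoch="memory_element")
        p = ConditionMatrix(p, d2.condition_labels, epoch="preparation_element")
    return m, p


@dataclass
class MixingSolution:
    """Fitted mixing coefficients with restart statistics."""

    a: float
    b: float
    mi_min: float
    mi_original: float
    restarts: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    a_sd: float = 0.0
    b_sd: float = 0.0
    a_sd_all: float = 0.0
    b_sd_all: float = 0.0
    degenerate: bool = False

    @property
    def a_rounded(self) -> float:
        return round(self.a, 2)

    @property
    def b_rounded(self) -> float:
        return round(self.b, 2)


def _mi_objective(flat1: np.ndarray, flat2: np.ndarray, n_bins: int, binning: str):
    # catastrophic-cancellation floor: if an unmixed array's norm falls this
    # far below the norms of its ingredients, its entries are float noise and
    # its (spuriously low) MI must not be trusted
    scale1 = np.linalg.norm(flat1)
    scale2 = np.linalg.norm(flat2)

    def objective(ab: np.ndarray) -> float:
        a, b = ab
        det = 1.0 - a * b
        if abs(det) < _SINGULAR_TOL:
            return _PENALTY
        m = (flat1 - a * flat2) / det
        p = (flat2 - b * flat1) / det
        floor = 1e-8 / abs(det)
        if (
            np.linalg.norm(m) < floor * (scale1 + abs(a) * scale2)
            or np.linalg.norm(p) < floor * (scale2 + abs(b) * scale1)
        ):
            return _PENALTY
        if np.ptp(m) == 0 or np.ptp(p) == 0:
            return _PENALTY
        return mutual_information(m, p, n_bins=n_bins, binning=binning)

    return objective


def fit_mixing(
    d1,
    d2,
    n_restarts: int = 1000,
    bounds: tuple[float, float] = (-0.5, 1.5),
    grid_step: float = 0.02,
    seed: int | np.random.Generator = 0,
    binning: str = "width",
    converged_tol: float = 0.02,
) -> MixingSolution:
    """Estimate (a, b) by multi-start minimization of unmixed-element MI.

    A coarse grid over ``bounds`` locates the valley of the piecewise-constant
    MI landscape; ``n_restarts`` Nelder-Mead searches from random initial
    points (plus one from the best grid point) refine it.  The spread of
    (a, b) is reported both over all restarts and over restarts that reached
    within ``converged_tol`` bits of the best MI.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flat1, flat2 = _values(d1).ravel(), _values(d2).ravel()
    n_bins = sturges_bins(flat1.size)
    objective = _mi_objective(flat1, flat2, n_bins, binning)
    mi_orig = mutual_information(flat1, flat2, n_bins=n_bins, binning=binning)

    lo, hi = bounds
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid_mi = np.array([[objective((a, b)) for b in grid] for a in grid])
    gi, gj = np.unravel_index(np.argmin(grid_mi), grid_mi.shape)
    best = (grid[gi], grid[gj], grid_mi[gi, gj])

    starts = rng.uniform(lo, hi, size=(n_restarts, 2))
    if n_restarts > 0:
        starts[0] = best[:2]
    records = np.empty((len(starts), 3))
    for k, x0 in enumerate(starts):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
        )
        a_k = float(np.clip(res.x[0], lo, hi))
        b_k = float(np.clip(res.x[1], lo, hi))
        records[k] = (a_k, b_k, objective((a_k, b_k)))
        if records[k, 2] < best[2]:
            best = tuple(records[k])
    a_best, b_best, mi_min = best
    degenerate = mi_min >= mi_orig - 1e-6 or mi_min >= _PENALTY
    if degenerate:
        a_best, b_best, mi_min = 0.0, 0.0, mi_orig
    good = records[:, 2] <= mi_min + converged_tol if len(records) else np.zeros(0, bool)
    return MixingSolution(
        a=float(a_best),
        b=float(b_best),
        mi_min=float(min(mi_min, mi_orig)),
        mi_original=float(mi_orig),
        restarts=records,
        a_sd=float(records[good, 0].std()) if good.any() else 0.0,
        b_sd=float(records[good, 1].std()) if good.any() else 0.0,
        a_sd_all=float(records[:, 0].std()) if len(records) else 0.0,
        b_sd_all=float(records[:, 1].std()) if len(records) else 0.0,
        degenerate=bool(degenerate),
    )


@dataclass
class Subspace:
    """A neurons x d orthonormal basis spanning an information subspace."""

    basis: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def project(self, x: np.ndarray) -> np.ndarray:
        """Coordinates of columns-as-points data: (neurons x k) -> (d x k)."""
        return self.basis.T @ x

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.basis @ (self.basis.T @ x)


def build_subspace(element, label: str = "other", rank_tol: float = 1e-8) -> Subspace:
    """Orthonormal basis of an element's column space via thin SVD.

    Singular values below ``rank_tol`` times the largest are treated as zero
    when determining the dimension.
    """
    values = _values(element)
    u, s, _ = np.linalg.svd(values, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("cannot build a subspace from an all-zero element")
    rank = int(np.sum(s > rank_tol * s[0]))
    return Subspace(basis=u[:, :rank], label=label)


# ---------------------------------------------------------------------------
# single-trial unmixing
# ---------------------------------------------------------------------------

def _subtract_columns(trials: np.ndarray, labels: np.ndarray, element: ConditionMatrix, coef: float) -> np.ndarray:
    out = trials.copy()
    for lab in np.unique(labels):
        col = element.column(lab)
        out[:, labels == lab] -= coef * col[:, None]
    return out


def unmix_single_trials(
    d1_trials: np.ndarray,
    d2_trials: np.ndarray,
    labels: np.ndarray,
    m_bar: ConditionMatrix,
    p_bar: ConditionMatrix,
    a: float,
    b: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unmix single-trial activity with label-matched element columns.

    M1 = D1 - a P[:, c];  M2 = D2 - P[:, c];
    P1 = D1 - M[:, c];    P2 = D2 - b M[:, c],
    where c is each pseudo-trial's condition label. Matrices are
    neurons x pseudo-trials.
    """
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        m_bar.column(lab)  # raises KeyError if a label has no column
        p_bar.column(lab)
    m1 = _subtract_columns(d1_trials, labels, p_bar, a)
    m2 = _subtract_columns(d2_trials, labels, p_bar, 1.0)
    p1 = _subtract_columns(d1_trials, labels, m_bar, 1.0)
    p2 = _subtract_columns(d2_trials, labels, m_bar, b)
    return m1, m2, p1, p2


def unmix_error_trials(
    d1e: np.ndarray,
    d2e: np.ndarray,
    labels: np.ndarray,
    m_bar: ConditionMatrix,
    p_bar: ConditionMatrix,
    a: float,
    b: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unmix error-trial activity using correct-trial elements and coefficients."""
    return unmix_single_trials(d1e, d2e, labels, m_bar, p_bar, a, b)


def unmix_presaccade(d1_bar, ds_bar, **fit_kwargs):
    """Unmix Delay-1 against pre-saccade activity with the same machinery.

    Returns ``(solution, m_prime, s_bar)`` where the solution carries the
    coefficients (a', b') and s_bar is the unmixed pre-saccade element.
    """
    solution = fit_mixing(d1_bar, ds_bar, **fit_kwargs)
    m_prime, s_bar = unmix_pair(d1_bar, ds_bar, solution.a, solution.b)
    return solution, m_prime, s_bar


# ---------------------------------------------------------------------------
# uncorrelated-label generalization
# ---------------------------------------------------------------------------

def _conditional_probs(trial_labels_1, trial_labels_2, labels_1, labels_2):
    """Empirical p(c2 | c1) and p(c1 | c2) from the trial table."""
    l1 = np.asarray(trial_labels_1)
    l2 = np.asarray(trial_labels_2)
    joint = np.zeros((len(labels_1), len(labels_2)))
    for i, a in enumerate(labels_1):
        for j, b in enumerate(labels_2):
            joint[i, j] = np.sum((l1 == a) & (l2 == b))
    if joint.sum() == 0:
        raise ValueError("labels have non-overlapping support in the trial table")
    p2_given_1 = joint / np.maximum(joint.sum(axis=1, keepdims=True), 1)
    p1_given_2 = (joint / np.maximum(joint.sum(axis=0, keepdims=True), 1)).T
    return p2_given_1, p1_given_2


def _uncorrelated_elements(g1, g2, a, b, p2_given_1, p1_given_2, tol=1e-8, max_iter=100):
    """Fixed-point solve of G1 = L + a E[C|L], G2 = C + b E[L|C]."""
    l_mat, c_mat = g1.copy(), g2.copy()
    for _ in range(max_iter):
        l_new = g1 - a * (c_mat @ p2_given_1.T)
        c_new = g2 - b * (l_new @ p1_given_2.T)
        delta = np.linalg.norm(l_new - l_mat) + np.linalg.norm(c_new - c_mat)
        l_mat, c_mat = l_new, c_new
        if delta < tol:
            break
    return l_mat, c_mat


def unmix_uncorrelated(
    g1_bar: ConditionMatrix,
    g2_bar: ConditionMatrix,
    trial_labels_1,
    trial_labels_2,
    n_restarts: int = 200,
    bounds: tuple[float, float] = (-0.5, 1.5),
    grid_step: float = 0.05,
    seed: int | np.random.Generator = 0,
    translation_tol: float = 1e-10,
) -> tuple[ConditionMatrix, ConditionMatrix, MixingSolution]:
    """Recover subspaces for two possibly uncorrelated task variables.

    G1 (grouped by variable 1) and G2 (grouped by variable 2) are modelled as
    G1 = L + a E[C | L] and G2 = C + b E[L | C], with the conditional
    expectations taken under the empirical joint label distribution.  When
    the two labels are in one-to-one mapping this reduces exactly to
    :func:`unmix_pair`; when the labels are fully crossed with no net
    translation the expectations vanish and the optimization is skipped.

    The MI objective pairs the flattened elements element-wise when the two
    matrices have equal shape, and pairs per-neuron row means otherwise.
    """
    g1, g2 = g1_bar.values, g2_bar.values
    p2_given_1, p1_given_2 = _conditional_probs(
        trial_labels_1, trial_labels_2, g1_bar.condition_labels, g2_bar.condition_labels
    )
    e_c = g2 @ p2_given_1.T  # E[C | L] columns at (a, b) = 0
    e_l = g1 @ p1_given_2.T
    scale = max(np.linalg.norm(g1), np.linalg.norm(g2), 1.0)
    if (
        np.linalg.norm(e_c) < translation_tol * scale
        and np.linalg.norm(e_l) < translation_tol * scale
    ):
        sol = MixingSolution(a=0.0, b=0.0, mi_min=0.0, mi_original=0.0, degenerate=False)
        return (
            ConditionMatrix(g1, g1_bar.condition_labels, "location_element"),
            ConditionMatrix(g2, g2_bar.condition_labels, "feature_element"),
            sol,
        )

    same_shape = g1.shape == g2.shape

    def pair(l_mat, c_mat):
        if same_shape:
            return l_mat.ravel(), c_mat.ravel()
        return l_mat.mean(axis=1), c_mat.mean(axis=1)

    x0, y0 = pair(g1, g2)
    n_bins = sturges_bins(x0.size)
    mi_orig = mutual_information(x0, y0, n_bins=n_bins)

    def objective(ab):
        a, b = ab
        if abs(1.0 - a * b) < _SINGULAR_TOL:
            return _PENALTY
        l_mat, c_mat = _uncorrelated_elements(g1, g2, a, b, p2_given_1, p1_given_2)
        x, y = pair(l_mat, c_mat)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            return _PENALTY  # fixed point diverged for this (a, b)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return _PENALTY
        return mutual_information(x, y, n_bins=n_bins)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = bounds
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    best = (0.0, 0.0, mi_orig)
    for a in grid:
        for b in grid:
            mi = objective((a, b))
            if mi < best[2]:
                best = (a, b, mi)
    for x0_ in rng.uniform(lo, hi, size=(n_restarts, 2)):
        res = minimize(objective, x0_, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 100})
        mi = objective(res.x)
        if mi < best[2]:
            best = (float(res.x[0]), float(res.x[1]), mi)
    a_best, b_best, mi_min = best
    l_mat, c_mat = _uncorrelated_elements(g1, g2, a_best, b_best, p2_given_1, p1_given_2)
    sol = MixingSolution(a=a_best, b=b_best, mi_min=mi_min, mi_original=mi_orig)
    return (
        ConditionMatrix(l_mat, g1_bar.condition_labels, "location_element"),
        ConditionMatrix(c_mat, g2_bar.condition_labels, "feature_element"),
        sol,
    )


def gram_schmidt_subspaces(d1_bar, d2_bar) -> tuple[Subspace, Subspace]:
    """Orthogonal subspace pair: span(D1) and span(D2 minus its D1 projection).

    The alternative to MI unmixing discussed as a baseline: fix Delay-1
    activity as the first subspace and rotate each Delay-2 column to be
    orthogonal to it.
    """
    v1, v2 = _values(d1_bar), _values(d2_bar)
    first = build_subspace(v1, label="memory")
    if first.dim < v1.shape[1]:
        raise ValueError("D1 must have full column rank")
    residual = v2 - first.basis @ (first.basis.T @ v2)
    if np.linalg.norm(residual) < 1e-10 * max(np.linalg.norm(v2), 1.0):
        raise ValueError("D2 lies entirely inside span(D1); second subspace empty")
    second = build_subspace(residual, label="preparation")
    return first, second


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class MutualInfoUnmixer(BaseEstimator):
    """Estimator interface to the mixing-model fit.

    ``fit(D1, D2)`` estimates the mixing coefficients and stores the unmixed
    elements and their subspaces; ``transform(D1_trials, D2_trials, labels)``
    unmixes single-trial activity with the fitted coefficients.

    Parameters
    ----------
    n_restarts : int
        Number of random-initialization local searches (1,000 by default).
    bounds : (float, float)
        Box bounds for both coefficients.
    grid_step : float
        Step of the coarse grid scan that seeds the local searches.
    binning : str
        "width" (equal-width bins, default) or "frequency".
    random_state : int or Generator
        Seed for the restart initializations.

    Attributes
    ----------
    a_, b_ : float
        Fitted mixing coefficients.
    mi_min_ : float
        Minimized mutual information (bits).
    solution_ : MixingSolution
        Full restart record.
    memory_element_, preparation_element_ : ConditionMatrix
    memory_subspace_, preparation_subspace_ : Subspace
    """

    def __init__(
        self,
        n_restarts: int = 1000,
        bounds: tuple[float, float] = (-0.5, 1.5),
        grid_step: float = 0.02,
        binning: str = "width",
        random_state: int | None = 0,
    ):
        self.n_restarts = n_restarts
        self.bounds = bounds
        self.grid_step = grid_step
        self.binning = binning
        self.random_state = random_state

    def fit(self, d1_bar, d2_bar):
        d1_bar = self._as_condition_matrix(d1_bar)
        d2_bar = self._as_condition_matrix(d2_bar)
        sol = fit_mixing(
            d1_bar,
            d2_bar,
            n_restarts=self.n_restarts,
            bounds=self.bounds,
            grid_step=self.grid_step,
            seed=self.random_state,
            binning=self.binning,
        )
        m_bar, p_bar = unmix_pair(d1_bar, d2_bar, sol.a, sol.b)
        self.solution_ = sol
        self.a_, self.b_, self.mi_min_ = sol.a, sol.b, sol.mi_min
        self.memory_element_ = m_bar
        self.preparation_element_ = p_bar
        self.memory_subspace_ = build_subspace(m_bar, label="memory")
        self.preparation_subspace_ = build_subspace(p_bar, label="preparation")
        return self

    @staticmethod
    def _as_condition_matrix(m) -> ConditionMatrix:
        if isinstance(m, ConditionMatrix):
            return m
        m = np.asarray(m, float)
        return ConditionMatrix(m, np.arange(1, m.shape[1] + 1))

    def transform(self, d1_trials, d2_trials, labels):
        """Unmix single-trial activity; returns (M1, M2, P1, P2)."""
        return unmix_single_trials(
            np.asarray(d1_trials, float),
            np.asarray(d2_trials, float),
            labels,
            self.memory_element_,
            self.preparation_element_,
            self.a_,
            self.b_,
        )

    def transform_pseudopopulation(
        self, d1: PseudoPopulation, d2: PseudoPopulation
    ) -> dict[str, dict[str, np.ndarray]]:
        """Unmix train and test splits of two matched pseudo-populations."""
        out: dict[str, dict[str, np.ndarray]] = {}
        for name, idx in (("train", 0), ("test", 1)):
            mats1 = (d1.train, d1.test)[idx]
            mats2 = (d2.train, d2.test)[idx]
            m1, m2, p1, p2 = self.transform(mats1, mats2, d1.labels)
            out[name] = {"M1": m1, "M2": m2, "P1": p1, "P2": p2}
        return out
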