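"""Containers and I/O for binned spike-count population recordings.

The universal input is a :class:`PopulationDataset`: a trials x neurons x
time-bins tensor of spike counts, time-locked to target onset, plus a trial
table with target/distractor locations, outcome and saccade-onset times.
Downstream analyses operate on two derived objects:

* :class:`ConditionMatrix` -- neurons x conditions matrix of trial- and
  time-averaged, baseline-subtracted firing rates for one task epoch;
* :class:`PseudoPopulation` -- a surrogate simultaneous population built by
  sampling one trial per neuron per condition from separately recorded
  sessions, with disjoint train/test trial pools.

Rates are expressed in spikes/s (counts divided by the bin width) before any
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PopulationDataset",
    "EpochWindows",
    "ConditionMatrix",
    "PseudoPopulation",
    "read_dataset",
    "write_dataset",
    "condition_matrix",
    "build_pseudopopulation",
    "sample_pseudotrial_indices",
]

TRIAL_COLUMNS = [
    "trial_id",
    "session_id",
    "target_location",
    "distractor_location",
    "outcome",
    "saccade_onset_ms",
]


@dataclass
class PopulationDataset:
    """Binned spike counts with per-trial metadata.

    Parameters
    ----------
    counts : ndarray, shape (n_trials, n_neurons, n_bins)
        Spikes per bin. Integer for recorded/Poisson data; float is accepted
        for rate-mode simulator output.
    bin_width : float
        Bin width in ms.
    t_start : float
        Time of the left edge of bin 0, in ms relative to target onset
        (negative values are pre-target bins).
    trials : DataFrame
        One row per trial with columns ``trial_id, session_id,
        target_location, distractor_location, outcome, saccade_onset_ms``.
        ``outcome`` is ``"correct"`` or ``"error"`` (fixation-maintained,
        wrong-saccade trials); aborted-fixation trials are excluded at read
        time and must not appear here.
    t0_event : str
        Label of the event that time 0 is locked to.
    """

    counts: np.ndarray
    bin_width: float
    trials: pd.DataFrame
    t_start: float = 0.0
    t0_event: str = "target_onset"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(
                f"counts must be 3-d (trials, neurons, bins); got {self.counts.shape}"
            )
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.counts.min() < 0:
            raise ValueError("spike counts must be non-negative")
        if len(self.trials) != self.counts.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but counts has "
                f"{self.counts.shape[0]} trials"
            )
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns {missing}")
        same = np.flatnonzero(
            self.trials["target_location"].to_numpy()
            == self.trials["distractor_location"].to_numpy()
        )
        if same.size:
            raise ValueError(
                "distractor_location equals target_location on trial index "
                f"{same[0]} (trial_id={self.trials['trial_id'].iloc[same[0]]})"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_edges(self) -> np.ndarray:
        """Bin edges in ms relative to target onset, length n_bins + 1."""
        return self.t_start + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges[:-1] + self.bin_width / 2.0

    def rates(self) -> np.ndarray:
        """Firing rates in spikes/s, same shape as counts."""
        return self.counts / self.bin_width * 1000.0

    def correct_mask(self) -> np.ndarray:
        return (self.trials["outcome"] == "correct").to_numpy()

    def bins_in_window(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bins whose centers fall in the half-open window [lo, hi)."""
        c = self.bin_centers
        return np.flatnonzero((c >= lo) & (c < hi))

    def baseline_rate(self, window: tuple[float, float] = (-300.0, 0.0)) -> np.ndarray:
        """Per-neuron mean rate over the baseline window and all correct trials."""
        bins = self.bins_in_window(*window)
        if bins.size == 0:
            raise ValueError(f"baseline window {window} covers no bins")
        mask = self.correct_mask()
        return self.rates()[mask][:, :, bins].mean(axis=(0, 2))


@dataclass
class EpochWindows:
    """Named half-open task-epoch windows in ms.

    All windows are relative to target onset except ``pre_saccade``, which is
    relative to saccade onset on each trial. Two Delay-2 windows coexist:
    ``delay2`` (2000-2500 ms) is used for unmixing, ``selectivity_delay2``
    (2100-2600 ms) for the per-cell ANOVA classification.
    """

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fixation": (-300.0, 0.0),
            "target": (0.0, 300.0),
            "delay1": (800.0, 1300.0),
            "distractor": (1300.0, 1600.0),
            "delay2": (2000.0, 2500.0),
            "selectivity_delay1": (800.0, 1300.0),
            "selectivity_delay2": (2100.0, 2600.0),
            "pre_saccade": (-150.0, 0.0),
        }
    )
    # windows aligned to saccade onset rather than target onset
    saccade_aligned: frozenset[str] = frozenset({"pre_saccade"})

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.windows.items():
            if hi <= lo:
                raise ValueError(f"window {name!r} is empty: [{lo}, {hi})")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.windows[name]

    def __contains__(self, name: str) -> bool:
        return name in self.windows

    def is_saccade_aligned(self, name: str) -> bool:
        return name in self.saccade_aligned

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EpochWindows":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        epochs = cfg.get("epochs", cfg)
        default = cls()
        windows = dict(default.windows)
        for name, pair in epochs.items():
            windows[name] = (float(pair[0]), float(pair[1]))
        return cls(windows=windows)


DEFAULT_EPOCHS = EpochWindows()


@dataclass
class ConditionMatrix:
    """Neurons x conditions matrix of baseline-subtracted mean rates."""

    values: np.ndarray
    condition_labels: np.ndarray
    epoch: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (neurons x conditions)")
        if self.values.shape[1] != len(self.condition_labels):
            raise ValueError("one label per condition column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("condition matrix contains non-finite entries")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        return self.values.ravel()

    def column(self, label) -> np.ndarray:
        idx = np.flatnonzero(self.condition_labels == label)
        if idx.size == 0:
            raise KeyError(f"no condition column for label {label!r}")
        return self.values[:, idx[0]]


@dataclass
class PseudoPopulation:
    """Pseudo-simultaneous population activity for one epoch.

    ``train`` and ``test`` are neurons x pseudo-trials matrices sampled from
    disjoint underlying trial sets per neuron; provenance indices are kept so
    the disjointness is testable.
    """

    train: np.ndarray
    test: np.ndarray
    labels: np.ndarray
    n_per_condition: int
    train_trial_idx: np.ndarray | None = None  # (neurons, pseudo-trials)
    test_trial_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.train.shape != self.test.shape:
            raise ValueError("train and test must have identical shapes")
        if self.train.shape[1] != len(self.labels):
            raise ValueError("one label per pseudo-trial required")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _trials_csv_path(path: Path) -> Path:
    return path.with_suffix(".trials.csv")


def write_dataset(data: PopulationDataset, path: str | Path) -> None:
    """Write a dataset as an HDF5 container plus a companion trial-table CSV."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        counts = data.counts
        if np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.uint16)
        fh.create_dataset("counts", data=counts)
        fh.create_dataset("bin_width_ms", data=float(data.bin_width))
        fh.attrs["t0_event"] = data.t0_event
        fh.attrs["t_start_ms"] = float(data.t_start)
    data.trials.to_csv(_trials_csv_path(path), index=False)


def read_dataset(path: str | Path, drop_aborts: bool = True) -> PopulationDataset:
    """Read and validate a dataset written by :func:`write_dataset`.

    Trials whose outcome is neither ``correct`` nor ``error`` (aborted
    fixation) are dropped when ``drop_aborts`` is set.
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "counts" not in fh:
            raise ValueError(f"{path}: missing /counts array")
        counts = fh["counts"][()]
        if "bin_width_ms" not in fh:
            raise ValueError(f"{path}: missing /bin_width_ms scalar")
        bin_width = float(fh["bin_width_ms"][()])
        t0_event = str(fh.attrs.get("t0_event", "target_onset"))
        t_start = float(fh.attrs.get("t_start_ms", 0.0))
    csv_path = _trials_csv_path(path)
    if not csv_path.exists():
        raise ValueError(f"missing companion trial table {csv_path}")
    trials = pd.read_csv(csv_path)
    if len(trials) != counts.shape[0]:
        raise ValueError(
            f"{path}: counts has {counts.shape[0]} trials but the trial table "
            f"has {len(trials)} rows"
        )
    if drop_aborts:
        keep = trials["outcome"].isin(["correct", "error"]).to_numpy()
        trials = trials.loc[keep].reset_index(drop=True)
        counts = counts[keep]
    return PopulationDataset(
        counts=counts,
        bin_width=bin_width,
        trials=trials,
        t_start=t_start,
        t0_event=t0_event,
    )


# ---------------------------------------------------------------------------
# condition matrices
# ---------------------------------------------------------------------------

def _window_rates(
    data: PopulationDataset,
    window: str | tuple[float, float],
    epochs: EpochWindows,
) -> np.ndarray:
    """Per-trial mean rate in a window -> (n_trials, n_neurons).

    Saccade-aligned windows are resolved per trial using saccade_onset_ms.
    """
    if isinstance(window, str):
        lo, hi = epochs[window]
        saccade_aligned = epochs.is_saccade_aligned(window)
    else:
        lo, hi = window
        saccade_aligned = False
    rates = data.rates()
    if not saccade_aligned:
        bins = data.bins_in_window(lo, hi)
        if bins.size == 0:
            raise ValueError(f"window [{lo}, {hi}) covers no time bins")
        return rates[:, :, bins].mean(axis=2)
    saccade = data.trials["saccade_onset_ms"].to_numpy(dtype=float)
    out = np.full((data.n_trials, data.n_neurons), np.nan)
    for t in range(data.n_trials):
        if not np.isfinite(saccade[t]):
            continue
        bins = data.bins_in_window(saccade[t] + lo, saccade[t] + hi)
        if bins.size == 0:
            continue
        out[t] = rates[t, :, bins].mean(axis=0)
    return out


def condition_matrix(
    data: PopulationDataset,
    window: str | tuple[float, float] = "delay1",
    baseline: str | tuple[float, float] | None = "fixation",
    group_by: str = "target",
    epochs: EpochWindows = DEFAULT_EPOCHS,
    correct_only: bool = True,
) -> ConditionMatrix:
    """Trial- and time-averaged, baseline-subtracted activity per condition.

    Entry (i, c) is neuron i's mean rate over the window and all trials of
    condition c, minus its mean rate over the baseline window and all
    included trials.
    """
    if group_by not in ("target", "distractor"):
        raise ValueError("group_by must be 'target' or 'distractor'")
    label_col = f"{group_by}_location"
    mask = data.correct_mask() if correct_only else np.ones(data.n_trials, bool)
    win_rates = _window_rates(data, window, epochs)
    valid = mask & np.isfinite(win_rates).all(axis=1)
    labels = data.trials[label_col].to_numpy()
    cond_labels = np.unique(labels)
    cols = np.empty((data.n_neurons, len(cond_labels)))
    for j, lab in enumerate(cond_labels):
        sel = valid & (labels == lab)
        if not sel.any():
            raise ValueError(f"condition {lab!r} has zero usable trials")
        cols[:, j] = win_rates[sel].mean(axis=0)
    if baseline is not None:
        base_rates = _window_rates(data, baseline, epochs)
        cols -= base_rates[mask].mean(axis=0)[:, None]
    name = window if isinstance(window, str) else f"[{window[0]},{window[1]})"
    return ConditionMatrix(values=cols, condition_labels=cond_labels, epoch=name)


# ---------------------------------------------------------------------------
# pseudo-populations
# ---------------------------------------------------------------------------

def sample_pseudotrial_indices(
    data: PopulationDataset,
    n_per_condition: int,
    rng: np.random.Generator,
    group_by: str = "target",
    correct_only: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample per-neuron trial indices for train/test pseudo-trials.

    Each neuron's trial pool for each condition is split into two disjoint
    halves; pseudo-trials are drawn from each half independently (with
    replacement when the half is smaller than ``n_per_condition``).

    Returns ``(train_idx, test_idx, labels)`` where the index arrays have
    shape (n_neurons, n_conditions * n_per_condition). Neurons here share
    trials (sessions are pooled by stacking neurons), so the per-neuron index
    rows are identical per condition draw only when a neuron-specific pool is
    unavailable; the split is performed per neuron to keep the provenance
    contract explicit.
    """
    label_col = f"{group_by}_location"
    mask = data.correct_mask() if correct_only else np.ones(data.n_trials, bool)
    labels = data.trials[label_col].to_numpy()
    cond_labels = np.unique(labels[mask])
    n_pseudo = len(cond_labels) * n_per_condition
    train_idx = np.empty((data.n_neurons, n_pseudo), dtype=np.int64)
    test_idx = np.empty((data.n_neurons, n_pseudo), dtype=np.int64)
    pseudo_labels = np.repeat(cond_labels, n_per_condition)
    for j, lab in enumerate(cond_labels):
        pool = np.flatnonzero(mask & (labels == lab))
        if pool.size < 2:
            raise ValueError(
                f"condition {lab!r} has {pool.size} trial(s); at least 2 are "
                "needed to form disjoint train/test pools"
            )
        sl = slice(j * n_per_condition, (j + 1) * n_per_condition)
        for i in range(data.n_neurons):
            perm = rng.permutation(pool)
            half = pool.size // 2
            tr_pool, te_pool = perm[:half], perm[half:]
            train_idx[i, sl] = rng.choice(
                tr_pool, n_per_condition, replace=tr_pool.size < n_per_condition
            )
            test_idx[i, sl] = rng.choice(
                te_pool, n_per_condition, replace=te_pool.size < n_per_condition
            )
    return train_idx, test_idx, pseudo_labels


def pseudo_matrix(
    values: np.ndarray, trial_idx: np.ndarray
) -> np.ndarray:
    """Gather (n_trials, n_neurons) per-trial values into neurons x pseudo-trials."""
    n_neurons, n_pseudo = trial_idx.shape
    return values[trial_idx, np.arange(n_neurons)[:, None]]


def build_pseudopopulation(
    data: PopulationDataset,
    window: str | tuple[float, float] = "delay1",
    n_per_condition: int = 250,
    seed: int | np.random.Generator = 0,
    group_by: str = "target",
    baseline: str | tuple[float, float] | None = "fixation",
    epochs: EpochWindows = DEFAULT_EPOCHS,
    correct_only: bool = True,
) -> PseudoPopulation:
    """Build a pseudo-population of window-averaged single-trial activity.

    Activity is baseline-subtracted with the per-neuron grand baseline mean
    (the same normalization applied to condition matrices) so single trials
    and condition matrices live on a common scale.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    win_rates = _window_rates(data, window, epochs)  # (trials, neurons)
    if baseline is not None:
        base = _window_rates(data, baseline, epochs)
        base_mask = data.correct_mask() if correct_only else np.ones(data.n_trials, bool)
        win_rates = win_rates - base[base_mask].mean(axis=0)[None, :]
    train_idx, test_idx, labels = sample_pseudotrial_indices(
        data, n_per_condition, rng, group_by=group_by, correct_only=correct_only
    )
    return PseudoPopulation(
        train=pseudo_matrix(win_rates, train_idx),
        test=pseudo_matrix(win_rates, test_idx),
        labels=labels,
        n_per_condition=n_per_condition,
        train_trial_idx=train_idx,
        test_trial_idx=test_idx,
    )
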