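"""Network simulators producing population datasets with known structure.

Three generators are provided:

1. A ring **bump attractor** with separate working-memory and
   motor-preparation populations (80 rate units each, configurable overlap),
   a quadratic-then-linear transfer function, and optional divisive
   normalization that rescales the whole population every step so the mean
   rate stays at its baseline value.  A localized input during the target
   epoch ignites a memory bump; an input during the distractor epoch ignites
   a preparation bump at the same location label; the distractor itself
   drives the memory population at 50% strength with a different label.

2. A **linear subspace model**: 112 linear units whose recurrent matrix is
   built by eigendecomposition with 17 unit eigenvalues (1 baseline + 8
   memory + 8 preparation stable directions, remaining eigenvalues uniform
   on (0, 1)), the same input schedule, and the same divisive normalization.

3. A direct **parametric generator** with known ground-truth mixing
   coefficients, used for unmixing parameter-recovery tests.

The trial timeline mirrors the task: 500 ms fixation, 300 ms target, 1000 ms
Delay 1, 300 ms distractor, 1000 ms Delay 2, followed by a Go cue and a
saccade 150-300 ms later.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import ConditionMatrix, PopulationDataset, PseudoPopulation

__all__ = [
    "AttractorConfig",
    "LinearModelConfig",
    "ParametricGroundTruth",
    "phi",
    "step_attractor",
    "simulate_bump_attractor",
    "simulate_linear_model",
    "generate_parametric_dataset",
]

# task timeline in ms relative to target onset
T_FIX_START = -500.0
T_TARGET = (0.0, 300.0)
T_DISTRACTOR = (1300.0, 1600.0)
T_GO = 2600.0
T_END = 2900.0


def phi(x: np.ndarray, variant: str = "linear") -> np.ndarray:
    """Piecewise transfer function: 0 for x<0, x^2 on [0,1], then 4x-3.

    ``variant="sqrt"`` switches the upper branch to sqrt(4x-3); both branches
    are continuous with x^2 at x=1.
    """
    x = np.asarray(x, dtype=float)
    upper = 4.0 * x - 3.0
    if variant == "sqrt":
        upper = np.sqrt(np.maximum(upper, 0.0))
    elif variant != "linear":
        raise ValueError(f"unknown phi variant {variant!r}")
    return np.where(x < 0, 0.0, np.where(x <= 1.0, x * x, upper))


@dataclass
class AttractorConfig:
    """Bump attractor parameters.

    Units: ``tau``/``dt`` in ms; weights and inputs are dimensionless model
    rates; ``rate_scale`` converts a model rate of 1 into spikes/s for
    Poisson sampling.  Excitation is a rectangular ring kernel of half-width
    ``kernel_halfwidth`` with amplitude ``w_plus``; all other within-ring
    weights are ``w_minus``.  Amplitudes were calibrated once so that a
    10-adjacent-unit input sustains a stable bump.
    """

    tau: float = 20.0
    dt: float = 2.0
    n_memory: int = 80
    n_preparation: int = 80
    overlap_ratio: float = 0.0
    n_locations: int = 8
    units_per_location: int = 10
    kernel_halfwidth: int = 5
    w_plus: float = 0.13
    w_minus: float = -0.012
    # optional preparation-ring overrides (None -> same as memory ring);
    # a wider/stronger preparation kernel gives the preparation bump more
    # mass, deepening the divisive squeeze on the memory bump in Delay 2
    prep_w_plus: float | None = None
    prep_kernel_halfwidth: int | None = None
    background: float = 0.5
    input_strength: float = 1.0
    distractor_strength_frac: float = 0.5
    noise_sd: float = 0.05
    normalize: bool = True
    phi_variant: str = "sqrt"
    rate_scale: float = 2.0  # spikes/s per unit model rate
    bin_width: float = 50.0  # ms
    loading_offset: int = 0  # circular offset of the location->unit blocks
    # circular offset of the preparation-ring blocks; a value that is not a
    # multiple of units_per_location guarantees that no location's
    # preparation block coincides with any location's memory block, which is
    # what makes overlapping units genuinely mixed-selective
    prep_loading_offset: int = 35

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_ratio <= 1.0:
            raise ValueError("overlap_ratio must be in [0, 1]")
        if self.dt <= 0 or self.tau <= 0 or self.dt >= self.tau:
            raise ValueError("require 0 < dt < tau")
        if self.n_locations * self.units_per_location > self.n_memory:
            raise ValueError("input blocks do not fit in the population")

    @property
    def n_overlap(self) -> int:
        return int(round(self.overlap_ratio * min(self.n_memory, self.n_preparation)))

    @property
    def n_units(self) -> int:
        return self.n_memory + self.n_preparation - self.n_overlap

    def memory_indices(self) -> np.ndarray:
        return np.arange(self.n_memory)

    def preparation_indices(self) -> np.ndarray:
        # the last n_overlap memory units double as the first preparation units
        start = self.n_memory - self.n_overlap
        return np.arange(start, start + self.n_preparation)

    def build_weights(self) -> np.ndarray:
        """Recurrent matrix: ring kernels per population, summed on overlaps."""
        w = np.zeros((self.n_units, self.n_units))
        prep_w = self.prep_w_plus if self.prep_w_plus is not None else self.w_plus
        prep_hw = (
            self.prep_kernel_halfwidth
            if self.prep_kernel_halfwidth is not None
            else self.kernel_halfwidth
        )
        for idx, n_pop, wp, hw in (
            (self.memory_indices(), self.n_memory, self.w_plus, self.kernel_halfwidth),
            (self.preparation_indices(), self.n_preparation, prep_w, prep_hw),
        ):
            ring = np.arange(n_pop)
            dist = np.abs(ring[:, None] - ring[None, :])
            dist = np.minimum(dist, n_pop - dist)
            kernel = np.where(dist <= hw, wp, self.w_minus)
            w[np.ix_(idx, idx)] += kernel
        return w

    def build_loadings(self) -> tuple[np.ndarray, np.ndarray]:
        """(memory, preparation) loading matrices, n_units x n_locations.

        Location k drives ``units_per_location`` adjacent ring units starting
        at ``loading_offset + k * units_per_location`` in each population.
        """
        w_mem = np.zeros((self.n_units, self.n_locations))
        w_prep = np.zeros((self.n_units, self.n_locations))
        for k in range(self.n_locations):
            block = k * self.units_per_location + np.arange(self.units_per_location)
            mem_block = (self.loading_offset + block) % self.n_memory
            prep_block = (self.prep_loading_offset + block) % self.n_preparation
            w_mem[self.memory_indices()[mem_block], k] = 1.0
            w_prep[self.preparation_indices()[prep_block], k] = 1.0
        return w_mem, w_prep


def step_attractor(
    state: np.ndarray,
    w_rec: np.ndarray,
    drive: np.ndarray,
    config: AttractorConfig,
    rng: np.random.Generator | None = None,
    baseline_mean: float | None = None,
) -> np.ndarray:
    """One forward-Euler step of tau dr/dt = -r + phi(W r + I + sigma).

    ``state`` may be (units,) or (trials, units); ``drive`` is the summed
    external input W_in I (same shape).  With normalization on, the updated
    state is divided by alpha = mean(r)/baseline_mean, applied uniformly to
    every unit, so the population mean is restored exactly.
    """
    state = np.asarray(state, dtype=float)
    x = state @ w_rec.T + drive
    if rng is not None and config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=state.shape)
    new = state + (-state + phi(x, config.phi_variant)) * (config.dt / config.tau)
    if config.normalize:
        if baseline_mean is None:
            raise ValueError("baseline_mean required when normalization is on")
        mean = new.mean(axis=-1, keepdims=True)
        if np.any(mean == 0):
            raise ZeroDivisionError(
                "population mean is zero; cannot divisively normalize"
            )
        new = new * (baseline_mean / mean)
    return new


def _baseline_state(
    w_rec: np.ndarray, drive: np.ndarray, config: AttractorConfig, n_iter: int = 10000
) -> np.ndarray:
    """Homogeneous background fixed point r* = phi(row_sum * r* + bg).

    Solved by damped scalar iteration from r = 0 (the low-activity branch)
    rather than by dynamical settling: long noise-free integration can
    amplify floating-point asymmetries into spurious bumps when the uniform
    state is weakly unstable, whereas the analytic uniform state is exact.
    """
    row_sum = float(w_rec.sum(axis=1).mean())
    bg = float(np.mean(drive))
    r = 0.0
    for _ in range(n_iter):
        r_new = 0.5 * r + 0.5 * float(phi(row_sum * r + bg, config.phi_variant))
        if abs(r_new - r) < 1e-13:
            r = r_new
            break
        r = r_new
    return np.full(w_rec.shape[0], r)


def _trial_table(
    n_trials_per_condition: int,
    n_locations: int,
    locations_used: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    targets = np.repeat(locations_used, n_trials_per_condition)
    all_locs = np.arange(1, n_locations + 1)
    distractors = np.array(
        [rng.choice(all_locs[all_locs != t]) for t in targets]
    )
    saccade = T_GO + rng.uniform(150.0, 280.0, size=targets.size)
    return pd.DataFrame(
        {
            "trial_id": np.arange(targets.size),
            "session_id": 0,
            "target_location": targets,
            "distractor_location": distractors,
            "outcome": "correct",
            "saccade_onset_ms": np.round(saccade, 1),
        }
    )


def _rates_to_dataset(
    rate_traces: np.ndarray,
    trials: pd.DataFrame,
    config,
    rng: np.random.Generator,
    return_rates: bool,
) -> PopulationDataset:
    """Bin dt-resolution traces (trials, steps, units) into a dataset."""
    n_trials, n_steps, n_units = rate_traces.shape
    steps_per_bin = int(round(config.bin_width / config.dt))
    n_bins = n_steps // steps_per_bin
    binned = rate_traces[:, : n_bins * steps_per_bin].reshape(
        n_trials, n_bins, steps_per_bin, n_units
    ).mean(axis=2)
    rate_hz = np.maximum(binned, 0.0) * config.rate_scale  # (trials, bins, units)
    rate_hz = np.transpose(rate_hz, (0, 2, 1))  # (trials, units, bins)
    if return_rates:
        counts = rate_hz * (config.bin_width / 1000.0)
    else:
        counts = rng.poisson(rate_hz * (config.bin_width / 1000.0)).astype(np.uint16)
    return PopulationDataset(
        counts=counts,
        bin_width=config.bin_width,
        trials=trials,
        t_start=T_FIX_START,
    )


def simulate_bump_attractor(
    config: AttractorConfig | None = None,
    n_trials_per_condition: int = 100,
    seed: int = 0,
    locations_used: np.ndarray | None = None,
    return_rates: bool = False,
) -> PopulationDataset:
    """Simulate the bump attractor over full trials and bin to a dataset.

    ``locations_used`` restricts target labels to a subset of the input
    locations (e.g. 7 of 8, as in the recorded task); distractor labels are
    drawn from all locations other than each trial's target.
    """
    config = config or AttractorConfig()
    rng = np.random.default_rng(seed)
    locations_used = (
        np.arange(1, config.n_locations + 1)
        if locations_used is None
        else np.asarray(locations_used)
    )
    trials = _trial_table(n_trials_per_condition, config.n_locations, locations_used, rng)
    w_rec = config.build_weights()
    w_mem, w_prep = config.build_loadings()
    bg = np.full(config.n_units, config.background)
    r0 = _baseline_state(w_rec, bg, config)
    baseline_mean = float(r0.mean())

    times = np.arange(T_FIX_START, T_END, config.dt)
    n_steps = times.size
    n_trials = len(trials)
    tgt = trials["target_location"].to_numpy() - 1
    dst = trials["distractor_location"].to_numpy() - 1

    r = np.tile(r0, (n_trials, 1))
    traces = np.empty((n_trials, n_steps, config.n_units), dtype=np.float32)
    in_target = (times >= T_TARGET[0]) & (times < T_TARGET[1])
    in_distr = (times >= T_DISTRACTOR[0]) & (times < T_DISTRACTOR[1])
    mem_drive_tgt = config.input_strength * w_mem[:, tgt].T  # (trials, units)
    mem_drive_dst = (
        config.input_strength * config.distractor_strength_frac * w_mem[:, dst].T
    )
    prep_drive = config.input_strength * w_prep[:, tgt].T
    for s in range(n_steps):
        drive = bg[None, :].copy()
        if in_target[s]:
            drive = drive + mem_drive_tgt
        if in_distr[s]:
            drive = drive + mem_drive_dst + prep_drive
        r = step_attractor(r, w_rec, drive, config, rng=rng, baseline_mean=baseline_mean)
        traces[:, s] = r
    return _rates_to_dataset(traces, trials, config, rng, return_rates)


# ---------------------------------------------------------------------------
# linear subspace model
# ---------------------------------------------------------------------------

@dataclass
class LinearModelConfig:
    """Linear subspace model parameters.

    The recurrent matrix is Q diag(eigenvalues) Q^-1 with 17 unit
    eigenvalues: 1 baseline direction (entries uniform on (0, 1)) plus 8
    memory and 8 preparation directions (entries uniform on (1, 2), hence
    positive mean, so divisive normalization couples the two signals); the
    remaining eigenvalues are uniform on (0, 1) with standard-normal
    eigenvectors.
    """

    n_units: int = 112
    n_locations: int = 8
    tau: float = 20.0
    dt: float = 2.0
    input_strength: float = 0.12
    distractor_magnitude: float = 0.2
    noise_sd: float = 0.02
    normalize: bool = True
    rate_scale: float = 25.0
    bin_width: float = 50.0
    network_seed: int = 1234
    q: np.ndarray | None = field(default=None, repr=False)
    eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def build_network(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (W_rec, Q, eigenvalues); draws Q/eigenvalues if not given."""
        if self.q is None or self.eigenvalues is None:
            rng = np.random.default_rng(self.network_seed)
            n, k = self.n_units, self.n_locations
            q = rng.standard_normal((n, n))
            q[:, 0] = rng.uniform(0.0, 1.0, n)  # baseline direction
            q[:, 1 : 1 + 2 * k] = rng.uniform(1.0, 2.0, (n, 2 * k))
            eig = np.concatenate(
                [np.ones(1 + 2 * k), rng.uniform(0.0, 1.0, n - 1 - 2 * k)]
            )
            self.q, self.eigenvalues = q, eig
        if abs(np.linalg.det(self.q)) < 1e-300:
            raise ValueError("eigenvector matrix Q is singular")
        w = self.q @ np.diag(self.eigenvalues) @ np.linalg.inv(self.q)
        return w, self.q, self.eigenvalues

    def memory_vectors(self) -> np.ndarray:
        self.build_network()
        return self.q[:, 1 : 1 + self.n_locations]

    def preparation_vectors(self) -> np.ndarray:
        self.build_network()
        return self.q[:, 1 + self.n_locations : 1 + 2 * self.n_locations]


def simulate_linear_model(
    config: LinearModelConfig | None = None,
    n_trials_per_condition: int = 100,
    seed: int = 0,
    locations_used: np.ndarray | None = None,
    return_rates: bool = False,
) -> PopulationDataset:
    """Simulate the linear subspace model over full trials.

    Memory input (along the target location's memory eigenvector) is active
    during the target epoch; preparation input (along the matching
    preparation eigenvector) during the distractor epoch; the distractor
    itself drives the memory eigenvector of its own label at relative
    magnitude ``distractor_magnitude``.
    """
    config = config or LinearModelConfig()
    rng = np.random.default_rng(seed)
    locations_used = (
        np.arange(1, config.n_locations + 1)
        if locations_used is None
        else np.asarray(locations_used)
    )
    trials = _trial_table(n_trials_per_condition, config.n_locations, locations_used, rng)
    w_rec, q, _ = config.build_network()
    baseline_vec = q[:, 0]
    mem_vecs = config.memory_vectors()
    prep_vecs = config.preparation_vectors()

    times = np.arange(T_FIX_START, T_END, config.dt)
    n_trials = len(trials)
    tgt = trials["target_location"].to_numpy() - 1
    dst = trials["distractor_location"].to_numpy() - 1

    r = np.tile(baseline_vec, (n_trials, 1))
    baseline_mean = float(baseline_vec.mean())
    traces = np.empty((n_trials, times.size, config.n_units), dtype=np.float32)
    in_target = (times >= T_TARGET[0]) & (times < T_TARGET[1])
    in_distr = (times >= T_DISTRACTOR[0]) & (times < T_DISTRACTOR[1])
    drive_tgt = config.input_strength * mem_vecs[:, tgt].T
    drive_dst = config.input_strength * config.distractor_magnitude * mem_vecs[:, dst].T
    drive_prep = config.input_strength * prep_vecs[:, tgt].T
    dt_tau = config.dt / config.tau
    for s in range(times.size):
        drive = np.zeros_like(r)
        if in_target[s]:
            drive = drive + drive_tgt
        if in_distr[s]:
            drive = drive + drive_dst + drive_prep
        x = r @ w_rec.T + drive
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=r.shape)
        r = r + (-r + x) * dt_tau
        if config.normalize:
            mean = r.mean(axis=-1, keepdims=True)
            if np.any(mean == 0):
                raise ZeroDivisionError("population mean is zero during normalization")
            r = r * (baseline_mean / mean)
        traces[:, s] = r
    return _rates_to_dataset(traces, trials, config, rng, return_rates)


# ---------------------------------------------------------------------------
# parametric ground-truth generator
# ---------------------------------------------------------------------------

@dataclass
class ParametricGroundTruth:
    """Known mixing ground truth for recovery tests.

    Elements are drawn i.i.d. per entry.  The default distribution is
    lognormal(0, 1): condition-mean rate deviations in cortex are strongly
    skewed and heavy-tailed, and -- decisive here -- the mixing coefficients
    are only point-identified by mutual-information minimization when the
    latent elements are non-Gaussian (for Gaussian elements every
    decorrelating (a, b) pair leaves the unmixed arrays independent, so the
    optimum is a curve, not a point).  A "gaussian" option is kept for
    exercising exactly that degeneracy.
    """

    n_neurons: int = 226
    n_conditions: int = 7
    a: float = 0.12
    b: float = 0.65
    noise_sd: float = 0.5
    n_per_condition: int = 50
    element_scale: float = 1.0
    element_distribution: str = "lognormal"
    m_bar: np.ndarray | None = None
    p_bar: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.a * self.b == 1.0:
            raise ValueError("ground truth requires a*b != 1")

    def draw_element(self, rng: np.random.Generator) -> np.ndarray:
        shape = (self.n_neurons, self.n_conditions)
        if self.element_distribution == "lognormal":
            x = rng.lognormal(0.0, 1.0, shape)
        elif self.element_distribution == "gaussian":
            x = rng.standard_normal(shape)
        else:
            raise ValueError(f"unknown distribution {self.element_distribution!r}")
        return self.element_scale * x


def generate_parametric_dataset(
    gt: ParametricGroundTruth, seed: int = 0
) -> tuple[ConditionMatrix, ConditionMatrix, PseudoPopulation, PseudoPopulation]:
    """Draw independent Gaussian elements, mix them, and emit single trials.

    Returns ``(D1_bar, D2_bar, d1_pseudo, d2_pseudo)``: the noise-free mixed
    condition matrices D1 = M + a P, D2 = b M + P, and matched Delay-1 /
    Delay-2 pseudo-populations whose single trials are condition means plus
    i.i.d. Gaussian noise.  The drawn elements are stored back on ``gt``.
    """
    rng = np.random.default_rng(seed)
    if gt.m_bar is None:
        gt.m_bar = gt.draw_element(rng)
    if gt.p_bar is None:
        gt.p_bar = gt.draw_element(rng)
    labels = np.arange(1, gt.n_conditions + 1)
    d1 = gt.m_bar + gt.a * gt.p_bar
    d2 = gt.b * gt.m_bar + gt.p_bar
    d1_cm = ConditionMatrix(d1, labels, epoch="delay1")
    d2_cm = ConditionMatrix(d2, labels, epoch="delay2")

    n_pseudo = gt.n_conditions * gt.n_per_condition
    trial_labels = np.repeat(labels, gt.n_per_condition)
    cols = np.searchsorted(labels, trial_labels)

    def draw(cm: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, gt.noise_sd, size=(gt.n_neurons, n_pseudo))
        return cm[:, cols] + noise

    d1_pseudo = PseudoPopulation(
        train=draw(d1), test=draw(d1), labels=trial_labels,
        n_per_condition=gt.n_per_condition,
    )
    d2_pseudo = PseudoPopulation(
        train=draw(d2), test=draw(d2), labels=trial_labels,
        n_per_condition=gt.n_per_condition,
    )
    return d1_cm, d2_cm, d1_pseudo, d2_pseudo
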