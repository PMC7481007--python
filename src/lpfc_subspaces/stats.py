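"""Bootstrap comparisons, Hedges' g, shuffle tests, and ANOVA selectivity.

Two bootstrap distributions are compared by counting overlapping points:
with N bootstraps and X overlaps the estimated p-value is (1 + X)/(N + 1),
so non-overlapping distributions give p < 0.001 at N = 1000 and x% overlap
gives p of about x/100.  Effect sizes use Hedges' g with the small-sample
correction 1 - 3/(4(n1 + n2) - 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .datasets import EpochWindows, DEFAULT_EPOCHS, PopulationDataset, _window_rates

__all__ = [
    "BootstrapComparison",
    "bootstrap_pvalue",
    "hedges_g",
    "compare_bootstrap",
    "classify_selectivity",
    "shuffle_null",
]


def _overlap_count(d1: np.ndarray, d2: np.ndarray) -> int:
    """Number of overlapping points for a one-sided d1-greater comparison.

    Counts d1 points at or below max(d2) plus d2 points at or above min(d1)
    (the points of each distribution inside the overlap interval), capped at
    N.
    """
    x = int(np.sum(d1 <= d2.max()) + np.sum(d2 >= d1.min()))
    return min(x, len(d1))


def bootstrap_pvalue(dist1, dist2, variant: str = "interval") -> float:
    """Estimated p-value (1 + X)/(N + 1) from bootstrap-distribution overlap.

    The larger-mean distribution is treated as dist1.  ``variant="pairs"``
    uses a threshold-free overlap count: the fraction of random cross-pairs
    whose order contradicts the mean order, scaled to N.
    """
    d1 = np.asarray(dist1, float)
    d2 = np.asarray(dist2, float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("empty bootstrap distribution")
    if d1.size != d2.size:
        raise ValueError("bootstrap distributions must have equal length")
    if d1.mean() < d2.mean():
        d1, d2 = d2, d1
    n = d1.size
    if variant == "interval":
        x = _overlap_count(d1, d2)
    elif variant == "pairs":
        x = min(int(2 * np.sum(d1[:, None] <= d2[None, :]) / n), n)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return (1.0 + x) / (n + 1.0)


def hedges_g(dist1, dist2) -> float:
    """Bias-corrected standardized mean difference between two samples."""
    d1 = np.asarray(dist1, float)
    d2 = np.asarray(dist2, float)
    n1, n2 = d1.size, d2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per distribution")
    s1, s2 = d1.std(ddof=1), d2.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(correction * (d1.mean() - d2.mean()) / pooled)


@dataclass
class BootstrapComparison:
    """Summary of a bootstrap-distribution comparison."""

    p_estimate: float
    hedges_g: float
    mean1: float
    mean2: float
    n: int


def compare_bootstrap(dist1, dist2, variant: str = "interval") -> BootstrapComparison:
    d1 = np.asarray(dist1, float)
    d2 = np.asarray(dist2, float)
    return BootstrapComparison(
        p_estimate=bootstrap_pvalue(d1, d2, variant=variant),
        hedges_g=hedges_g(d1, d2),
        mean1=float(d1.mean()),
        mean2=float(d2.mean()),
        n=d1.size,
    )


def classify_selectivity(
    data: PopulationDataset,
    alpha: float = 0.05,
    epochs: EpochWindows = DEFAULT_EPOCHS,
) -> pd.DataFrame:
    """Per-neuron selectivity class from location x epoch ANOVAs.

    Spike counts are averaged over the Delay 1 (800-1300 ms) and Delay 2
    (2100-2600 ms) selectivity windows on correct trials.  A two-way ANOVA
    (target location x task epoch) and two one-way location ANOVAs (one per
    delay) assign, in order of precedence:

    * ``pure_preparation`` -- one-way significant in Delay 2 but not Delay 1;
    * ``mixed`` -- significant location and epoch main effects plus a
      significant location x epoch interaction;
    * ``pure_memory`` -- no significant interaction, and either location
      tuning in both delays or significant location and epoch main effects;
    * ``none`` otherwise.

    Returns a DataFrame with the class label and the underlying p-values.
    """
    mask = data.correct_mask()
    r1 = _window_rates(data, "selectivity_delay1", epochs)[mask]
    r2 = _window_rates(data, "selectivity_delay2", epochs)[mask]
    loc = data.trials["target_location"].to_numpy()[mask]
    classes = np.unique(loc)
    groups1 = [r1[loc == c] for c in classes]
    groups2 = [r2[loc == c] for c in classes]
    for c, g in zip(classes, groups1):
        if len(g) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
    # vectorized one-way ANOVAs over neurons
    p_d1 = f_oneway(*groups1, axis=0).pvalue
    p_d2 = f_oneway(*groups2, axis=0).pvalue

    n_neurons = data.n_neurons
    records = []
    loc_series = np.concatenate([loc, loc])
    epoch_series = np.concatenate(
        [np.zeros(loc.size, dtype=int), np.ones(loc.size, dtype=int)]
    )
    for i in range(n_neurons):
        df = pd.DataFrame(
            {
                "rate": np.concatenate([r1[:, i], r2[:, i]]),
                "loc": loc_series,
                "epoch": epoch_series,
            }
        )
        try:
            fit = ols("rate ~ C(loc) * C(epoch)", data=df).fit()
            table = anova_lm(fit, typ=2)
            p_loc = float(table.loc["C(loc)", "PR(>F)"])
            p_epoch = float(table.loc["C(epoch)", "PR(>F)"])
            p_inter = float(table.loc["C(loc):C(epoch)", "PR(>F)"])
        except Exception:
            p_loc = p_epoch = p_inter = 1.0
        sig_d1, sig_d2 = p_d1[i] < alpha, p_d2[i] < alpha
        if sig_d2 and not sig_d1:
            label = "pure_preparation"
        elif p_loc < alpha and p_epoch < alpha and p_inter < alpha:
            label = "mixed"
        elif p_inter >= alpha and (
            (sig_d1 and sig_d2) or (p_loc < alpha and p_epoch < alpha)
        ):
            label = "pure_memory"
        else:
            label = "none"
        records.append(
            {
                "neuron": i,
                "label": label,
                "p_location": p_loc,
                "p_epoch": p_epoch,
                "p_interaction": p_inter,
                "p_oneway_delay1": float(p_d1[i]),
                "p_oneway_delay2": float(p_d2[i]),
            }
        )
    return pd.DataFrame.from_records(records)


def shuffle_null(
    statistic,
    data,
    shuffler,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation null for an arbitrary statistic.

    ``statistic(data)`` computes the observed value; ``shuffler(data, rng)``
    returns a resampled copy under the null.  Significance at the 95th
    percentile (one-sided, greater) as used throughout.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = statistic(data)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = statistic(shuffler(data, rng))
    percentile = 100.0 * np.mean(null < observed)
    return {
        "observed": observed,
        "null": null,
        "percentile": float(percentile),
        "significant": observed > np.percentile(null, 95.0),
    }
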