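"""End-to-end analysis orchestration.

``run_pipeline`` drives the full chain -- load or simulate a dataset, build
condition matrices, fit the mixing model, derive subspaces, run subspace and
full-space decoding, and compute the geometry summaries -- and writes a
machine-readable summary plus tabular outputs.  A single root seed spawns
named substreams so every stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, decoding, geometry, simulate, unmixing
from .datasets import EpochWindows, DEFAULT_EPOCHS

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    dataset_path: str | None = None  # HDF5 path; mutually exclusive with simulator
    simulator: str | None = "bump"  # "bump" | "linear" | None
    n_trials_per_condition: int = 60
    locations_used: list[int] | None = None
    seed: int = 0
    out_dir: str = "results"
    # analysis options
    n_restarts: int = 1000
    bounds: tuple[float, float] = (-0.5, 1.5)
    bin_ms: float = 100.0
    n_repeats: int = 3
    n_per_condition: int = 40
    epochs: EpochWindows = field(default_factory=EpochWindows)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        epochs = EpochWindows.from_yaml(path) if "epochs" in cfg else EpochWindows()
        cfg.pop("epochs", None)
        if "bounds" in cfg:
            cfg["bounds"] = tuple(cfg["bounds"])
        return cls(epochs=epochs, **cfg)


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Writes ``summary.json``, decoding grids and restart tables as CSV under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _substreams(config.seed, ["simulate", "pseudopop", "fit", "decode", "boot"])

    # -- stage: data -----------------------------------------------------
    if config.dataset_path:
        data = datasets.read_dataset(config.dataset_path)
    elif config.simulator == "bump":
        data = simulate.simulate_bump_attractor(
            n_trials_per_condition=config.n_trials_per_condition,
            seed=int(rngs["simulate"].integers(2**31)),
            locations_used=config.locations_used,
        )
    elif config.simulator == "linear":
        data = simulate.simulate_linear_model(
            n_trials_per_condition=config.n_trials_per_condition,
            seed=int(rngs["simulate"].integers(2**31)),
            locations_used=config.locations_used,
        )
    else:
        raise ValueError("either dataset_path or a simulator must be given")

    # -- stage: condition matrices & unmixing ----------------------------
    d1 = datasets.condition_matrix(data, "delay1", epochs=config.epochs)
    d2 = datasets.condition_matrix(data, "delay2", epochs=config.epochs)
    unmixer = unmixing.MutualInfoUnmixer(
        n_restarts=config.n_restarts,
        bounds=config.bounds,
        random_state=int(rngs["fit"].integers(2**31)),
    ).fit(d1, d2)
    sol = unmixer.solution_
    pd.DataFrame(sol.restarts, columns=["a", "b", "mi"]).to_csv(
        out / "restarts.csv", index=False
    )
    np.savetxt(out / "memory_basis.csv", unmixer.memory_subspace_.basis, delimiter=",")
    np.savetxt(
        out / "preparation_basis.csv", unmixer.preparation_subspace_.basis, delimiter=","
    )

    # -- stage: decoding -------------------------------------------------
    decode_seed = int(rngs["decode"].integers(2**31))
    grids = {}
    for name, proj in [
        ("full", None),
        ("memory", unmixer.memory_subspace_),
        ("preparation", unmixer.preparation_subspace_),
    ]:
        grid = decoding.cross_temporal_decode(
            data,
            projection=proj,
            bin_ms=config.bin_ms,
            n_per_condition=config.n_per_condition,
            n_repeats=config.n_repeats,
            seed=decode_seed,
            epochs=config.epochs,
        )
        grids[name] = grid
        pd.DataFrame(grid.accuracy, index=grid.times, columns=grid.times).to_csv(
            out / f"decoding_{name}.csv"
        )

    d1w, d2w = config.epochs["delay1"], config.epochs["delay2"]

    # -- stage: geometry -------------------------------------------------
    angles = geometry.principal_angles(
        unmixer.memory_subspace_, unmixer.preparation_subspace_
    )
    angles.null_distributions = geometry.random_subspace_null(
        d1.n_neurons,
        unmixer.preparation_subspace_,
        unmixer.memory_subspace_.dim,
        n=200,
        seed=rngs["boot"],
    )
    lw = geometry.loading_weights(
        unmixer.memory_subspace_, unmixer.preparation_subspace_,
        n_shuffles=200, seed=rngs["boot"],
    )
    pseudo1 = datasets.build_pseudopopulation(
        data, "delay1", n_per_condition=config.n_per_condition,
        seed=rngs["pseudopop"], epochs=config.epochs,
    )
    pseudo2 = datasets.build_pseudopopulation(
        data, "delay2", n_per_condition=config.n_per_condition,
        seed=rngs["pseudopop"], epochs=config.epochs,
    )
    var_expl = {
        "delay1_memory": geometry.variance_explained(pseudo1.train.T, unmixer.memory_subspace_),
        "delay1_preparation": geometry.variance_explained(pseudo1.train.T, unmixer.preparation_subspace_),
        "delay2_memory": geometry.variance_explained(pseudo2.train.T, unmixer.memory_subspace_),
        "delay2_preparation": geometry.variance_explained(pseudo2.train.T, unmixer.preparation_subspace_),
    }
    eff_dim = geometry.effective_dimensionality(
        pseudo1.train.T @ unmixer.memory_subspace_.basis
    )
    m1, m2, p1, p2 = unmixer.transform(pseudo2.train, pseudo2.train, pseudo2.labels)[:4]
    ratio = geometry.inter_intra_ratio(
        (m2.T @ unmixer.memory_subspace_.basis),
        pseudo2.labels,
        n_boot=200,
        n_per_cluster=config.n_per_condition,
        seed=rngs["boot"],
    )

    # population-mean rate per epoch (the divisive-normalization signature)
    rates = data.rates()
    mask = data.correct_mask()
    epoch_means = {
        name: float(
            rates[mask][:, :, data.bins_in_window(*config.epochs[name])].mean()
        )
        for name in ("fixation", "delay1", "delay2")
    }

    summary = {
        "a": sol.a,
        "b": sol.b,
        "mi_min_bits": sol.mi_min,
        "mi_original_bits": sol.mi_original,
        "memory_decoding_delay1": grids["memory"].block_mean(d1w),
        "memory_decoding_delay2": grids["memory"].block_mean(d2w),
        "preparation_decoding_delay1": grids["preparation"].block_mean(d1w),
        "preparation_decoding_delay2": grids["preparation"].block_mean(d2w),
        "full_decoding_delay1": grids["full"].block_mean(d1w),
        "full_decoding_delay2": grids["full"].block_mean(d2w),
        "full_decoding_cross_delay": grids["full"].block_mean(d1w, d2w),
        "chance": grids["full"].chance,
        "principal_angles_deg": angles.angles.tolist(),
        "principal_angles_significant": angles.significant().tolist(),
        "loading_weight_correlation": lw.correlation,
        "loading_weight_correlation_significant": bool(lw.correlation_significant()),
        "n_exclusive_neurons": int(lw.exclusive_memory.sum() + lw.exclusive_preparation.sum()),
        "inter_intra_ratio_memory_delay2": ratio.ratio,
        "effective_dimensionality_memory": eff_dim,
        "variance_explained": var_expl,
        "population_mean_rate": epoch_means,
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
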