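# lpfc-subspaces

Tools for decomposing delay-period neural population activity into two
minimally dependent low-dimensional subspaces — one carrying working-memory
information, one carrying motor-preparation information — together with the
cross-temporal decoding, subspace-geometry and statistical analyses that
characterize those subspaces, and two divisive-normalization network
simulators that generate population data with the assumed structure.

The intended users are systems neuroscientists analyzing binned spike-count
recordings from delayed-response tasks with an intervening distractor
(trials × neurons × time-bins, plus a trial table of target location,
distractor location, outcome and saccade onset).

## The method

Let `D1` and `D2` be neurons × conditions matrices of trial- and
time-averaged, baseline-subtracted activity in the two delay periods. The
model treats them as a 2 × 2 mixture of a working-memory element `M` and a
motor-preparation element `P`:

```
D1 = M + a·P
D2 = b·M + P
```

`a` is the fraction of preparation activity already present in Delay 1, and
`b` the fraction of memory activity persisting into Delay 2. The
coefficients are estimated by minimizing the histogram mutual information
(Sturges-rule binning, base-2 log) between the flattened unmixed elements,
using a coarse grid scan plus 1,000 Nelder–Mead restarts. The orthonormal
column bases of the recovered `M` and `P` define the memory and preparation
subspaces; single-trial activity is unmixed with the label-matched element
columns (`M1 = D1 − a·P[:,c]`, `M2 = D2 − P[:,c]`, etc.) and evaluated with
a pooled-covariance LDA decoder, principal angles, inter-to-intra cluster
distance ratios, per-neuron loading weights, bootstrap-overlap p-values and
Hedges' g.

## Worked example

Simulate a ring bump attractor with divisive normalization (160 rate
units: 80 memory + 80 preparation), fit the mixing model, and decode:

```python
import numpy as np
from lpfc_subspaces import (
    AttractorConfig, simulate_bump_attractor, condition_matrix,
    MutualInfoUnmixer, cross_temporal_decode,
)

data = simulate_bump_attractor(AttractorConfig(), n_trials_per_condition=100,
                               seed=1, locations_used=np.arange(1, 8))
d1 = condition_matrix(data, "delay1")
d2 = condition_matrix(data, "delay2")
est = MutualInfoUnmixer(n_restarts=200, random_state=1).fit(d1, d2)
print(f"a={est.a_:.2f} b={est.b_:.2f} "
      f"MI {est.solution_.mi_original:.2f} -> {est.mi_min_:.2f} bits")

grid = cross_temporal_decode(data, projection=est.memory_subspace_,
                             bin_ms=250, n_per_condition=100, seed=1)
print(f"memory-subspace decoding: Delay1 {grid.block_mean((800, 1300)):.1f}% "
      f"Delay2 {grid.block_mean((2000, 2500)):.1f}% (chance {grid.chance:.1f}%)")
```

Output:

```
a=0.13 b=0.68 MI 0.54 -> 0.10 bits
memory-subspace decoding: Delay1 62.1% Delay2 52.0% (chance 14.3%)
```

The fitted `b < 1` says the memory element's condition-mean magnitude is
smaller in Delay 2, once preparation activity has emerged under the
population-mean constraint; the unmixing reduces the dependence between
the two elements from 0.54 to 0.10 bits, and the memory subspace carries
target information in both delays.

A command-line interface wraps the same pipeline:

```
lpfc-subspaces simulate --model bump --seed 1 --out data.h5
lpfc-subspaces unmix --dataset data.h5 --restarts 1000 --out solution.json
lpfc-subspaces decode --dataset data.h5 --projection solution.memory_basis.csv --out grid.csv
lpfc-subspaces run --seed 1 --out results/
```

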