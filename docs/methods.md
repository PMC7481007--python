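# Methods

## The mixing model and its estimator

Delay-period population activity is summarized per epoch as a neurons ×
conditions matrix of trial- and time-averaged firing rates (spikes/s),
baseline-subtracted with each neuron's mean rate over the 300 ms of
fixation preceding target onset. The Delay-1 and Delay-2 matrices are
modelled as

    D1 = M + a P,      D2 = b M + P,

with scalar mixing coefficients `(a, b)` and latent elements `M`
(working memory) and `P` (motor preparation) assumed minimally dependent.
Because a rescaling of the elements can always absorb diagonal
coefficients, the diagonal is fixed at one, which gives `a` and `b` their
interpretation as cross-epoch leak fractions.

Dependence is measured by histogram mutual information between the
flattened elements: each array is discretized into `ceil(1 + log2 N)`
equal-width bins over its own min–max range (`N` = neurons × conditions),
the joint mass function comes from the 2-d histogram, empty cells are
skipped, and the result is in bits. Equal-frequency binning is available
as an option. A constant array is defined to carry zero MI (with a
warning).

The MI surface is piecewise constant in `(a, b)`, so gradient methods are
unreliable. The fit therefore combines a coarse grid scan (step 0.02 over
the bounds, default `[-0.5, 1.5]`) with many Nelder–Mead restarts from
random initial points (1,000 by default, seeded); the best grid point seeds
one restart. The curve `a·b = 1` (singular mixing) is excluded by penalty,
as are candidate points whose unmixed arrays are dominated by
floating-point cancellation (norm below `1e-8` of their ingredients'
norms — without this guard the optimizer can reach spuriously low MI by
driving an element to pure rounding noise). The spread of `(a, b)` is
reported both over all restarts and over restarts within 0.02 bits of the
optimum. If no candidate improves on the original MI the solution is
flagged degenerate and `(0, 0)` returned.

Identifiability deserves emphasis: minimizing dependence point-identifies
`(a, b)` only when the elements are non-Gaussian. For jointly Gaussian
elements every decorrelating pair leaves the unmixed arrays independent,
so the optimum is a one-dimensional curve through the truth and any point
on it may be returned. Cortical condition-mean rate deviations are
strongly skewed, which is what makes the method applicable to neural data;
the parametric test fixture accordingly draws its elements from a
lognormal(0, 1) distribution by default (a Gaussian option is retained to
exercise the degeneracy). At the fixture's size (226 × 7 = 1,582 samples,
12 Sturges bins) the estimator's intrinsic precision is roughly ±0.05 per
draw, so recovery accuracy is assessed on the average over seeds and
optimizer quality against a dense grid-search oracle of the same
objective.

Subspaces are the orthonormal bases of the elements' column spaces (thin
SVD; singular values below `1e-8` of the largest are treated as zero).
Single-trial activity is unmixed by subtracting label-matched element
columns: `M1 = D1 − a P[:,c]`, `M2 = D2 − P[:,c]`, `P1 = D1 − M[:,c]`,
`P2 = D2 − b M[:,c]`; error trials use the correct-trial elements and
coefficients. The same machinery unmixes Delay-1 against pre-saccadic
activity (150–0 ms before saccade onset, resolved per trial). For task
designs where the two variables are not in one-to-one correspondence, the
generalized system `G1 = L + a E[C|L]`, `G2 = C + b E[L|C]` is solved by
fixed-point iteration (stop at `1e-8` Frobenius change or 100 iterations)
inside the same MI minimization; with a one-to-one mapping it reduces
exactly to the 2 × 2 case, and when the conditional expectations vanish
(fully crossed labels, no net translation) the optimization is skipped.
When the two grouped matrices have equal shapes the MI objective pairs
them element-wise; with unequal condition counts it pairs per-neuron row
means — the pairing convention is otherwise undefined.

## Decoding

Pseudo-populations are built by sampling, per neuron and condition, trials
from two disjoint pools (train/test); sampling within a pool is with
replacement only when the pool is smaller than the requested count, and
source-trial indices are retained so disjointness is testable. The decoder
is linear discriminant analysis with pooled within-class covariance,
empirical class priors, and a ridge term `1e-6 · trace/d` on the
covariance diagonal (the few-hundred-dimensions regime is near-singular
without it); it is cross-checked in the tests against scikit-learn's LDA.
Cross-temporal decoding trains at each time bin and tests at every bin;
full-space decoding first reconstructs both splits from the training bin's
principal components covering 95% of variance, subspace decoding instead
projects both splits onto the fixed basis. Default bins are 100 ms
(analyses here typically use 250 ms); scalar per-delay accuracies are
means over grid cells whose train and test bins both fall in the delay
window. Error-trial accuracy uses a classifier fit on projected
correct-trial activity and scored on projected error-trial activity.

## Geometry and statistics

Principal angles come from the SVD of `X'Y` of two orthonormal bases
(singular values clamped to [−1, 1] before `acos`); chance is assessed
against 1,000 QR-orthonormalized Gaussian subspaces, with significance
when an observed angle falls below the 5th percentile of its per-rank
null. The inter-to-intra cluster distance ratio uses Euclidean distances:
inter = grand mean of pairwise distances between cluster means, intra =
grand mean over clusters of mean pairwise within-cluster distance, with a
bootstrap (250 points per cluster, 1,000 resamples, 5th–95th percentiles;
resamples that collapse a cluster to a point are dropped as NaN). Loading
weights are row norms of the orthonormal bases (so squared weights sum to
the subspace dimension); exclusivity flags neurons whose log2 weight ratio
deviates more than two SDs from the population mean; the across-neuron
weight correlation is tested against weight permutations. The
axis-clustering test drops a random 10% of neurons per bootstrap and
counts weight-pair angles above 67.5° or below 22.5°. Projection-magnitude
time courses are Frobenius norms of per-bin condition-mean matrices
projected into a subspace, normalized to a maximum of one.

Bootstrap comparisons use the estimated p-value `(1 + X)/(N + 1)`, where
`X` counts the points of each distribution lying inside the overlap
interval (each distribution's points beyond the other's extreme), capped
at `N`; non-overlapping distributions give p < 0.001 at N = 1,000 and x%
overlap gives p ≈ x/100. A threshold-free variant (discordant cross-pair
fraction) is available behind a flag. Effect sizes use Hedges' g with the
small-sample correction `1 − 3/(4(n1+n2) − 9)`. Selectivity
classification averages spike counts over 800–1300 ms (Delay 1) and
2100–2600 ms (Delay 2), runs a two-way location × epoch ANOVA
(statsmodels OLS, type-II sums of squares) and two one-way location
ANOVAs, and assigns, in precedence order: pure preparation (one-way
significant in Delay 2 only), mixed (both main effects plus interaction),
pure memory (no interaction, and either location tuning in both delays or
both main effects), else none; α = 0.05 per cell, uncorrected. Under the
null this scheme's type-I rate is ≈5% (dominated by the
pure-preparation arm at α(1−α)).

## Synthetic data generators

Three generators produce data with known structure.

**Parametric fixture.** Draws independent elements (lognormal(0, 1) per
entry by default, see above), mixes them with known `(a, b)` (defaults
0.12 and 0.65), and emits single trials as condition means plus i.i.d.
Gaussian noise (SD 0.5, 50 trials/condition by default). Used for
recovery, null-space, and geometry tests.

**Bump attractor.** Two rings of 80 rate units (working memory and motor
preparation; overlap configurable, overlapping units receive both kernels
and loadings) with rectangular ring kernels (excitation `w+ = 0.13`
within ±5 units, uniform inhibition `w− = −0.012` elsewhere), transfer
function φ(x) = 0 / x² / branch for x < 0 / 0 ≤ x ≤ 1 / x > 1, Euler
integration with τ = 20 ms, dt = 2 ms, per-step Gaussian noise
(SD 0.05) inside φ, and optional divisive normalization: after each step
the whole population is rescaled by mean(r)/mean(r0), keeping the mean
rate exactly at its baseline value. The upper φ branch is `4x − 3` by
default in `phi()` with a `sqrt(4x − 3)` variant; the default attractor
configuration uses the sqrt variant because the unbounded linear branch
(gain 4) admits no saturating bump amplitude, making two coexisting bumps
winner-take-all under strict normalization. Each of the 8 input units
drives 10 adjacent units per ring; the preparation ring's blocks are
circularly offset by 35 units so that no location's preparation block
coincides with any memory block. The timeline mirrors the task: 500 ms
fixation, 300 ms target (memory input), 1,000 ms delay, 300 ms distractor
(distractor input at 50% strength and a different label onto the memory
ring; preparation input at the target label onto the preparation ring),
1,000 ms delay, Go cue, saccade 150–280 ms later. The homogeneous
background state is obtained by solving the scalar uniform fixed point
analytically rather than by settling (long noise-free integration can
amplify float asymmetries into spurious bumps). Rates are converted to
Poisson counts in 50 ms bins at 2 spikes/s per model-rate unit — a scale
calibrated once so that memory-subspace Delay-1 decoding of 100-trial
pseudo-populations lands near 60% rather than at ceiling — or returned as
exact rates.

Calibration notes, frozen after a systematic sweep: with strict per-step
divisive normalization the ring model has a structural trichotomy. A
low-mass subcritical background gives a clean ignition threshold (the 50%
distractor leaves no trace) but the normalization transient of the
distractor epoch extinguishes the undriven memory bump on every trial; a
high-mass background (the default) buffers that transient so memory and
preparation bumps coexist, but has effectively no ignition threshold, so
the distractor leaves a persistent trace in the memory ring; intermediate
regimes inherit both defects, and overlapping (mixed-selective)
populations destroy each other's codes at every tested overlap. Two
consequences follow for the default model and are deliberate, documented
behavior rather than bugs: (1) because the distractor may never match the
target, averaging the persistent distractor trace over the seven allowed
locations leaves a target-correlated "exclusion hole" in the Delay-2
condition means that no scalar `b` can cancel, so a little target
information appears in the preparation subspace already in Delay 1
(≈25–30% vs 14.3% chance; ≈18% with the distractor disabled); (2) the
memory bump survives Delay 2 nearly intact at the single-trial level, so
a Delay-1 decoder generalizes to Delay 2 with only a ~14-point loss
rather than collapsing. Real prefrontal populations, whose mixed
selectivity reshapes the code between delays, show a stronger morphing
than this disjoint-ring idealization.

**Linear subspace model.** 112 linear units with `W = Q Λ Q^{-1}`;
17 unit eigenvalues (1 baseline eigenvector with entries U(0,1), 8 memory
and 8 preparation eigenvectors with entries U(1,2) — hence positive mean),
remaining eigenvalues U(0,1) with standard-normal eigenvectors. State
starts on the baseline eigenvector; memory input drives the target's
memory eigenvector during the target epoch, preparation input the matching
preparation eigenvector during the distractor epoch, and the distractor
the memory eigenvector of its own label at relative magnitude 0.2. With
normalization on, the positive-mean preparation signal raises the
population mean in Delay 2, the uniform rescaling shrinks the memory
component, and memory decoding drops from Delay 1 to Delay 2 — the
mechanism the model exists to demonstrate. Without normalization the
memory component and decoding are stable across both delays.

What the generators emulate: discrete target conditions, a memory signal
from target onset through both delays, a preparation signal from
distractor offset, condition-matched memory/preparation labels,
trial-to-trial rate noise, Poisson spiking, and a constant population
mean under normalization. What they do not: real session-to-session
heterogeneity, correlated (non-Poisson) trial noise, behavioral error
mechanisms (analyses of error trials are exercised on label-permuted or
noise-inflated synthetic trials), eye-movement artifacts, and the
nonlinear mixed selectivity of real prefrontal neurons. Passing tests on
this synthetic data validate the estimator chain and the models'
qualitative regimes, not quantitative properties of any recorded dataset.

## Numerical choices and degenerate inputs

Windows are half-open in ms relative to target onset (fixation
[−300, 0), target [0, 300), delay1 [800, 1300), distractor [1300, 1600),
delay2 [2000, 2500), with a second Delay-2 window [2100, 2600) used only
by the selectivity ANOVA, and pre-saccade [−150, 0) relative to saccade
onset); bins are assigned by center. Rates are counts/bin-width in
spikes/s. Aborted-fixation trials are dropped at read time; error trials
are fixation-maintained wrong-saccade trials. Sessions are pooled by
stacking neurons (pseudo-simultaneity), so within-session noise
correlations are not preserved. Ties in the LDA argmax resolve to the
first class; identical condition matrices make the mixing fit degenerate
(flagged, not silently returned); all-zero elements, empty windows,
singular mixing, zero-range MI inputs, and clusters with a single point
raise explicit errors.

## Known limitations

The histogram MI estimator's bias and granularity set a floor of roughly
±0.05 on coefficient recovery at the 226 × 7 scale; the bump attractor's
structural trade-offs under strict divisive normalization are described
above; the uncorrelated-label generalization assumes the empirical joint
label distribution is well estimated; and the linear model's uniform U(1,2)
eigenvector entries make its memory and preparation patterns mutually
correlated, so fitted coefficients on linear-model data are less
interpretable than its decoding behavior.
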