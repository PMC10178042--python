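# Methods

## Model and procedure

The classifier is a single-hidden-layer extreme learning machine. Given
training features X (n×d) and integer labels, the hidden layer computes
H = σ(Xω + b) with sigmoid σ, input weights ω ∈ ℝ^{d×L} and biases b ∈ ℝ^L;
output weights β ∈ ℝ^{L×K} solve min‖Hβ − T‖_F for one-hot targets T via the
SVD-based Moore–Penrose pseudo-inverse (numpy's default relative cutoff).
Prediction is the argmax over the K output columns, ties broken toward the
lowest class index. One-hot {0,1} coding with argmax decoding is the
conventional multiclass ELM setup; no ridge term is used by default (an
optional Tikhonov parameter exists for ill-conditioned H, e.g. L close to n).

Hidden parameters are either drawn from U(−1, 1) — the common ELM convention,
which also fixes the optimizer search box — or supplied by an optimizer.
The optimizers search the packed vector (ω column-major, then b), dimension
dL + L, inside [−1, 1]^{dL+L}, minimising the misclassification rate of the
resulting ELM on an evaluation partition. After optimization the best (ω, b)
are refitted on the full training partition.

### Honey badger algorithm

Population of N agents; per iteration t = 1..t_max each agent proposes one
move (digging with probability 1/2, honey otherwise, see README for the
update equations) and is replaced only on improvement; the prey is the best
position found so far. Constants: density factor α = C·exp(−t/t_max) with
C = 2; digging strength β_h = 6 (the defaults of the algorithm's original
formulation, which this package adopts since the study describing the
coupling does not restate the update equations). Choices the formulation
leaves open, resolved here:

- the random factors r₂ (smell), r₃, r₄, r₅ (digging) and r₇ (honey) are
  drawn independently per dimension, consistent with the per-dimension smell
  intensity; a scalar-draw variant was considered and rejected as it couples
  all coordinates of a move;
- the neighbour term in S = (xᵢ − xᵢ₊₁)² wraps around (the last agent pairs
  with the first) so S is defined for every agent;
- d² in the smell intensity carries an ε = 1e−12 guard against agents sitting
  exactly on the prey;
- all proposals are clamped to the box, since positions decode to ELM weights
  that must stay in the sampled range.

### Adaptive t-distribution mutation (tHBA)

After the HBA moves, each agent is independently mutated with probability
P (default 0.8, the value reported to work best in the motivating study):
x' = x + x ⊙ t_df, with one Student-t draw per dimension and degrees of
freedom equal to the (1-based) iteration number, so df ≥ 1 always holds.
Acceptance is greedy by default — the study's phrase "update the badger
position" is ambiguous, and greedy acceptance makes the mutation a pure
improvement operator; `mutation_accept="always"` preserves the alternative
reading. Note the mutation is multiplicative in x, so the origin is a fixed
point; with weights spread over [−1, 1] this is harmless in practice.

Each run spawns **two independent RNG streams** from its seed: one for the
HBA moves, one for the mutation stage (gates and t-draws). Hence tHBA with
P = 0 consumes exactly the same move stream as plain HBA and reproduces its
trajectory bit-for-bit — a structural reduction property the tests assert.

### GA baseline

Real-coded: tournament selection (size 3), arithmetic crossover (rate 0.8),
per-gene Gaussian mutation (rate 0.05, σ = 0.1·(ub − lb)), elitism of one.
These are textbook defaults; the motivating study specifies only the shared
population size (50) and iteration count (300).

Evaluation accounting is exact for all three optimizers: N initial
evaluations plus every proposal evaluated (N per HBA iteration, plus one per
accepted mutation gate for tHBA, N−1 offspring per GA generation); the
reported `n_evaluations` equals the number of fitness calls, which the tests
verify with a counting wrapper. Best-so-far histories are non-increasing by
construction.

## Preprocessing

- Calibration: R = (R_raw − R_dark)/(R_white − R_dark), element-wise, with an
  explicit error naming the first channel where white and dark coincide.
- MSC: each spectrum is OLS-regressed on a reference (channel-wise mean of
  the *training* rows only — fitting it on all rows would leak test
  information into the transform) and the affine fit inverted:
  (x − a)/b. |b| < 1e−12 raises, since such a spectrum carries no signal
  correlated with the reference and the inversion would blow up. Negative b
  is valid.
- SNV: per-row standardisation with the n−1 (sample) standard deviation, the
  conventional SNV definition; this makes the worked 3-point example exact.
- Min-max: per-spectrum rescaling onto [0, 1] by default. Whether the
  original study normalised per spectrum or per wavelength is unstated;
  row-wise was chosen as the default because it is invariant to per-sample
  affine scatter (the nuisance the treatment targets), and a per-channel
  axis option is exposed.

## Synthetic data generator

The generator emulates ROI-averaged SWIR reflectance spectra of melon
surfaces. The shared base curve is a smooth quadratic baseline plus positive
Gaussian bumps (σ = 40 nm) at 1125, 1340, 1801, 2000, 2313, 2370 nm and
negative ones at 1020, 1269, 1552, 1929, 2432, 2466 nm — the peak/valley
morphology of real melon-surface spectra. Class identity enters as a
reflectance offset shaped by a Hann window supported on 1493–2038 nm, the
window where real pesticide classes separate; default offsets
(0, 0.05, 0.125, 0.075, 0.10) put the no-residue class strictly lowest and
Malathion strictly highest, with the remaining classes at distinct
intermediate levels, so the generator reproduces the documented ordering of
class means over 1493–1663 nm. Each sample is a·mean_k + b + ε with
a ~ U(0.95, 1.05), b ~ U(−0.02, 0.02) (per-sample scatter of a few percent,
typical of diffuse-reflectance measurements) and i.i.d. Gaussian ε with
sd 0.01 — roughly 1% reflectance noise, a realistic SNR for a cooled SWIR
line-scan camera after ROI averaging.

What the generator does **not** emulate: wavelength-correlated noise,
water-band saturation, chemistry-specific absorption of the four pesticides,
instrument drift between sessions, and pixel-level image structure. Passing
tests therefore demonstrate that the algorithms behave correctly on data
with the documented statistical structure, not that the headline accuracies
on real melon spectra are reproduced — those spectra are not public.

With these defaults the five classes are linearly separable in the
233-channel space (an LDA cross-check reaches 100% test accuracy) yet
overlapping enough that a small randomly-initialised ELM errs; this is the
regime in which optimizing (ω, b) visibly helps, which is the point of the
package's end-to-end comparisons.

## Experiment protocol

Stratified per-class split with train fraction 0.75: test size is floored
per class, remainder to train, so 160/class splits exactly into 120 train +
40 test (600/200 overall). The split precedes preprocessing so MSC statistics
can be fitted on the training partition alone. Hidden-layer sizes default to
the studied configuration: 135 for the plain ELM benchmark, 120 for every
optimized ELM.

Fitness evaluation set: the historical protocol scored optimizer candidates
on the test set itself, which leaks test labels into model selection. The
default mode (`validation`) instead carves a stratified 80/20 validation
split out of the training set; `test_paper_mode` reproduces the historical
behaviour for fidelity experiments. Both are tested.

Seeding: a pipeline seed feeds a `SeedSequence` that derives independent
sub-seeds for generation, splitting, validation splitting, ELM
initialisation and the optimizer, so runs are bit-reproducible and paired
model comparisons (same seed → same data and partitions) are exact.

## Problem sizes used in tests and the acceptance script

Sphere benchmarks run 5 dimensions, N = 20, t_max = 100, 10 seeds; the
tHBA-vs-HBA comparison grants plain HBA extra iterations until its
evaluation count matches tHBA's, making the budgets equal. End-to-end
comparisons run the full default generator (800 spectra, 233 channels) with
a reduced search budget — L = 40, N = 10, t_max = 30, 5 paired seeds —
which keeps a complete paired comparison to a few seconds per run while
leaving the optimizer enough budget to beat random initialisation. The
well-separated regime (noise sd 0.005, i.e. adjacent class offsets ≥ 5× the
noise) is where test accuracy is expected to exceed 0.80 at this budget;
under default noise the same pipeline lands around 0.75 and the comparison
against plain ELM is the meaningful check.

## Known limitations

- The digging/honey equations follow the original HBA formulation; other
  published variants differ in how r₃–r₇ are drawn and in prey update timing.
- The t-mutation is multiplicative, so coordinates at exactly 0 never move
  by mutation alone (the HBA moves still relocate them).
- Zero-denominator metric cells (a class never predicted) report 0 with a
  RuntimeWarning rather than raising; small synthetic runs can produce them.
- At full study scale (d = 233, L = 120 → 28,080-dimensional search,
  N = 50, t_max = 300) one run costs tens of thousands of 600×120
  pseudo-inverses — minutes of compute; the library supports it, but the
  test suite intentionally runs reduced budgets.
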