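# Methods

## Problem setting

Sustained-phonation voice recordings yield a table of perturbation measures
(jitter and shimmer families, noise-to-harmonics ratios, nonlinear dynamics
measures) per recording, with a binary disease status per subject and
several recordings per subject. The classification task is to predict the
status of a held-out recording. The package's job is the surrounding
machinery: preprocessing, RBF-SVM hyperparameter search by swarm
metaheuristics, and a complete confusion-matrix evaluation.

## Preprocessing

The chain is PCA first, Z-scoring of the principal-component scores second.
PCA operates on the raw feature units; the covariance uses the population
convention (divide by `n`), as does the Z-score's standard deviation
(`s = √(Σ(xᵢ−x̄)²/n)`). The number of retained components is the smallest
`k` whose leading eigenvalues reach `variance_threshold` (default 0.95) of
the total variance; a fixed `k` can be given instead. Eigenvector signs are
fixed so each component's largest-magnitude loading is positive, making
outputs identical across linear-algebra backends. Zero-variance columns are
dropped with a warning by default (`on_zero_variance="raise"` to abort).

Both transforms are fitted on the training split only and applied frozen to
validation folds and the test split; the no-leakage property is asserted in
the test suite by refitting from the training rows alone.

Standardizing *before* PCA is the more common order; this package keeps
PCA-first because that is the published order of the workflow it
re-implements. PCA on raw heterogeneous units retains the directions that
dominate raw variance, so this order is only sensible when the
discriminative signal lives there — see the generator notes below.

## SVM and solver

Soft-margin binary SVM in dual form: maximize `Σαᵢ − ½αᵀQα` with
`Qᵢⱼ = yᵢyⱼK(xᵢ,xⱼ)`, subject to `0 ≤ αᵢ ≤ C` and `Σαᵢyᵢ = 0`. Kernels:
Gaussian `exp(−‖x−y‖²/φ²)` (tuned through `γ = 1/φ²`), polynomial
`(x·y + a)^b`, and linear. The decision function is
`f(x) = Σαᵢyᵢ K(xᵢ,x) + b`; the predicted label is `sign(f)`, with an exact
zero mapped to +1 (documented tie rule).

The solver is sequential minimal optimization with maximal-violating-pair
selection of the first index and second-order (maximal-gain) selection of
the second — deterministic, hence training is invariant to row permutation
up to exact ties. The pair curvature is `Kᵢᵢ + Kⱼⱼ − 2Kᵢⱼ`, floored at
1e−12 for degenerate pairs. The inner loop is numba-compiled; a pure-numpy
fallback implements the identical algorithm.

Numerical choices (module constants, not per-call guesses):

* internal stopping tolerance on the KKT violation gap: 1e−6; the
  guaranteed post-condition for returned models is the looser 1e−3;
* multipliers ≤ 1e−8 are treated as zero and pruned from the stored model;
* bias: mean of `yᵥ − Σαᵢyᵢ K(xᵢ,xᵥ)` over free support vectors
  (`0 < α < C`); with no free vectors, the midpoint of the KKT-valid
  interval;
* update budget: `10n + 1000` pair updates, plus a stagnation stop when a
  pair update improves the dual objective by less than
  `1e−9 · (1 + |objective|)`. Well-conditioned problems converge far below
  the budget (the suite verifies the dual optimum against a generic QP to
  1e−4 relative); the budget only truncates pathological corners of the
  hyperparameter box (nearly-constant kernel at a hard margin), where the
  truncated iterate is still a usable classifier and the model is flagged
  `converged=False` with a warning. The budget was sized so a full swarm
  search stays in the minutes range; larger budgets change no reported
  result, only the time spent in those corners.

## Optimizers

All three methods maximize a black-box fitness over a box, share one seeded
`numpy` Generator, clip positions to the box after every move, and keep
personal-best/global-best memory, so the reported best fitness is
nondecreasing by construction.

* **PSO** as printed in the classic formulation: no inertia damping
  (`w = 1` by default, configurable), `r₁, r₂ ~ U(0,1)` fresh per particle
  per dimension. Because the undamped update can diverge, velocities are
  clamped to `velocity_clamp_fraction · (upper − lower)` (default 0.5) — a
  standard stabilization, stated here as a deliberate deviation from the
  bare equations.
* **CS**: each nest proposes `x + α·L(λ)` with Mantegna-generated Lévy
  steps (`λ = 1.5`, `α = levy_alpha_scale · range`, default scale 0.01),
  greedily replacing a *randomly chosen* nest; then the abandonment walk
  perturbs each coordinate with probability `Pa` by `N(0,1)·(xⱼ − xₖ)`,
  where `j, k` are random permutations of the swarm, offset so `j ≠ k`
  rowwise (keeping the realized perturbation frequency exactly `Pa`);
  acceptance is greedy per nest.
* **Hybrid CS-PSO**: the combination scheme is genuinely open in the
  source workflow, so both plausible readings are implemented. The default
  `interleaved` strategy runs, per generation: PSO update → Lévy
  perturbation of every particle with greedy acceptance → abandonment of
  the worst `⌈Pa·P⌉` particles (velocities reset to zero). The
  `sequential` strategy runs CS for the first half of the iteration budget
  and PSO, warm-started from the nests, for the second. Neither is claimed
  to be "the" published scheme.

Random-stream discipline: a stage disabled by its parameter
(`levy_alpha_scale = 0`, `pa = 0`) consumes no random numbers, so the
hybrid with both off reproduces plain PSO bit for bit — a tested
equivalence.

Defaults are the reference operating point: population 18, 120 iterations,
`c₁ = 1.3`, `c₂ = 1.87`, `Pa = 0.262`. Search box for SVM tuning:
`log₂C ∈ [−5, 15]`, `log₂γ ∈ [−15, 3]` (standard RBF grid extents).
Boundary handling is clipping, chosen over reflection for the simplest
exactly-testable contract.

## Fitness and pipeline

The tuning objective is the mean stratified 5-fold cross-validated accuracy
of an SVM trained at the candidate `(2^{log₂C}, 2^{log₂γ})` on the training
split; folds are fixed by the run seed, so fitness is deterministic within
a run and cached by exact position. Fitness ties in the global-best update
break toward the lexicographically smaller position — smaller `log₂C`, then
smaller `log₂γ`, i.e. the more regularized, smoother model. Per fold, the
squared-distance matrices are precomputed once and only re-exponentiated
per candidate, which is what makes a 120-generation swarm search over
~5,000 SVM fits per run take seconds.

The experiment chain: data → stratified holdout split (default 20%;
`round(fraction · n_c)` rows per class, or whole subjects per side in
`subject-grouped` mode) → preprocessing fitted on train → swarm search →
final refit on the full training split at the best point → nine-metric
holdout report. Every number in the report is a pure function of
(config, seed); reruns are byte-identical, which the suite asserts.
Row-stratified splitting is the default (matching the re-implemented
workflow's apparent protocol); subject-grouped splitting is the recommended
option for honest subject-level generalization, since recordings of one
subject are correlated.

## Metrics

The nine scores are computed from integer counts in exact
`fractions.Fraction` arithmetic (MCC's square root as a final float).
A zero denominator yields an explicit `None` ("undefined"), never a silent
zero, so degenerate classifiers are visible in reports.

`reconstruct_confusion_matrix` enumerates all `(tp, fp, fn, tn)` with a
given total `n` (`O(n³)` compositions; instant at n = 39) and keeps those
whose metrics match every supplied printed value within half a unit of its
last printed decimal. This turns published, rounded result rows into exact
integer confusion matrices — the package's audit tool for results tables.
With n = 195 recordings, printed accuracies of 97.4359% and 92.3077% are
the rationals 38/39 and 36/39, pinning the test-set size to 39 (a 20%
holdout); the three benchmark rows used in the tests invert uniquely to
(10, 0, 1, 28), (10, 2, 1, 26) and (8, 1, 6, 24).

## Synthetic data generator

`generate_voice_like` reproduces the *structure* of the public PD voice
table: 23 affected and 8 healthy subjects, 6–7 recordings each (~195 rows),
22 positive-valued correlated features, subject-level grouping. The latent
model is a 4-factor Gaussian (communality 0.7, unit column variances) with
a per-subject random offset carrying a `within_subject_correlation`
fraction (default 0.3) of the variance. The disease shift lies inside the
factor span and is weighted by each feature's raw measurement scale, then
calibrated (by bisection, accounting for the between-class variance
inflation) so that the distance between class means *after per-column
standardization* equals `class_separation`. Latent values map through a
monotone softplus onto positive feature-specific scales loosely matching
voice-measurement magnitudes.

Two modelling notes. First, voice perturbation measures really do co-vary
in families, and disease shifts those families jointly — the factor
structure mimics that. Second, placing the signal in the directions that
dominate raw variance is deliberate: it is the regime in which
PCA-before-scaling (the re-implemented preprocessing order) retains class
information at all. The generator therefore shows what the pipeline does
on data *for which its design is appropriate*; it does not model MDVP
measurement physics, heavy-tailed measurement noise, or disease signal
hidden in low-variance features — on such data, PCA-first preprocessing
would discard signal, and passing tests here say nothing about that case.
The default `class_separation = 4` gives a learnable but imperfect problem;
the well-separated benchmark used in end-to-end tests sets it to 6.

`generate_blobs` is the trivial fixture: two isotropic unit Gaussians at
`±(separation/2)·e₁`.

## Problem sizes used in the checks

The acceptance script and end-to-end tests run the full reference operating
point (population 18, 120 generations, 5-fold CV) on the default ~195-row
synthetic table: about 5,000 SVM fits per run, roughly 10 s each on one
core. Sphere-benchmark convergence uses 20 seeded runs per method; Lévy
tail recovery uses 1e5 samples; the abandonment-rate check uses 1e4
coordinate draws; solver-vs-QP verification uses 25 random duals with
n ≤ 30 (where a generic SLSQP solve is reliable).

## Known limitations

* The tuned pipeline optimizes the Gaussian kernel only (the 2-D
  `(log₂C, log₂γ)` box); polynomial and linear kernels are available in
  `svm_core` but not wired into the search.
* No probability calibration, multiclass support, regression mode, or
  sigmoid kernel.
* The CV-accuracy objective is a plateau-rich, noisy-free surface; on
  easily separable data large regions tie at 1.0 and the reported best
  `(C, γ)` is then the tie-break's choice, not a unique optimum.
* Single 20%-holdout evaluation mirrors the re-implemented protocol; for
  honest variance estimates on real data, rerun over seeds (the CLI's
  `--seed`) and aggregate, and prefer `--split-mode subject-grouped`.
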