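# Methods

## The selection pipeline

The package implements hybrid filter/wrapper feature selection for binary
classification over wide, non-negative feature matrices (rows = samples,
columns = named features, label 1 = the malignant-like class).

**Filter stage** (`StatisticalPrefilter`), applied to the training
partition only, in order:

1. *Chi-square relevance.* For feature j and class k, the observed value is
   the class-conditional column sum O_kj and the expected value
   E_kj = (class prior) × (column total); the score is Σ_k (O−E)²/E. This
   value-sum contingency form needs no binning and is exact for rectified
   (ReLU-like) activations, which are the intended input; it requires
   non-negative values and both classes present, and assigns 0 to
   constant-zero columns. The top `k_chi2` features are kept
   (default ⌈10% of P⌉ — the retention depth is a tuning knob; the method
   itself does not fix it).
2. *Correlation pruning.* A greedy scan in feature-index order drops any
   feature whose |Pearson r| with an already-kept feature exceeds
   `corr_threshold` (default 0.95). This removes near-duplicate columns
   before impurity importances are computed, because correlated features
   split impurity credit arbitrarily between themselves. Zero-variance
   columns are treated as r = 0 and logged.
3. *RFE.* A StandardScaler + L2 logistic regression (C = 1, lbfgs) is
   refit after removing, one per iteration, the feature with the smallest
   absolute standardized coefficient (ties: lowest index), down to `k_rfe`
   survivors. Survivors are ranked 1..k by descending final |coefficient|,
   the eliminated rest in reverse elimination order, so ranks are a
   tie-free permutation.
4. *Tree importance.* Random-forest mean decrease in impurity (`n_trees` =
   100, seeded), normalized to sum to 1; all-zero for unsplittable data.
5. *Combiner.* Per-criterion top-k masks merged under a policy. Default
   `hybrid`: chi² top-k ∩ (RFE survivors ∪ tree top-k), falling back to the
   union when the intersection has < 2 features, and to the single best
   chi² feature as a last resort — the candidate pool is never empty.
   `union`, `intersection` and `chi2-only` are available.

**Wrapper stage** (`SalpSwarmSelector`). N agents hold positions in
[lb, ub]^d over the candidate pool (d = pool size; dimensions outside the
pool are frozen unselected). Each iteration:

- c₁(t) = 2·exp(−(4t/t_max)²) — strictly decreasing, c₁(0) = 2;
- the leader (agent 1) resamples around the food source F: per dimension,
  with c₂, c₃ ~ U[0,1], offset = c₁((ub−lb)c₂ + lb) and the sign is +
  when c₃ < 0.5, − otherwise, then clamped to the box. The textbook
  formulation of this update writes the branch condition as c₃ ≤ 0, which
  for c₃ ∈ [0,1] would select the “+” branch with probability zero; the
  0.5 threshold (configurable `branch_threshold`) restores the obviously
  intended two-sided search;
- followers average element-wise with their already-updated predecessor in
  chain (index) order, so leader movement propagates within one iteration;
- positions are binarized at `binarize_threshold` (default 0.5); an
  all-false mask falls back to the single largest coordinate, so every
  evaluated subset is non-empty;
- fitness = RMSE of pooled held-out predictions from stratified 5-fold CV
  of a standardized 5-nearest-neighbour classifier on the masked columns
  of the *training partition only*. For 0/1 labels this equals
  √(1 − CV accuracy) exactly (asserted to 1e−12 in the tests). KNN was
  chosen as the internal scorer because it is cheap, parameter-light and
  scale-controlled by the per-fold standardizer; it is configurable.
  Fitness carries no explicit feature-count penalty; parsimony comes from
  binarization plus the pre-filter.
- F is updated *elitist*: only a strictly better fitness replaces it. The
  per-iteration best-so-far history is therefore non-increasing, which the
  test suite asserts for every optimizer on every seeded run. Repeated
  masks are cached within a run, so converged populations cost little.

One leader is used (the single-leader update is what the chain model
defines; the count is configurable). "Population = 10" is read as 10
agents; independent restarts are the evaluation harness's job.

## Baselines

`ParticleSwarmSelector`, `GeneticSelector`, `GreyWolfSelector` and
`MultiVerseSelector` share the pre-filter, binarization, fitness, elitist
tracking and history contract, and differ only in the move rule, each per
its canonical published formulation:

- **PSO** (Kennedy & Eberhart 1995, with inertia damping): v ← w·v +
  C1·r1·(pbest − x) + C2·r2·(gbest − x), w multiplied by wDamp per
  iteration. Defaults w = 1, wDamp = 0.99, C1 = 1, C2 = 2.
- **GA**: binary chromosomes (a chromosome *is* a mask — no binarization),
  Boltzmann-roulette parent selection with pressure β = 8
  (p ∝ exp(−β·cost/worst)), uniform crossover producing 2·round(pc·N/2)
  offspring (pc = 0.8), round(pm·N) mutants (pm = 0.3) with per-bit flip
  rate μ = 0.02, then elitist truncation to the best N. γ = 0.2 is the
  real-coded crossover blend range and is inert for binary chromosomes; it
  is kept for parameter parity and documented as such.
- **GWO** (Mirjalili et al. 2014): the three best-ever wolves
  (alpha/beta/delta) encircle; a decays linearly 2 → 0.
- **MVO** (Mirjalili et al. 2016): white/black-hole exchange by roulette
  over normalized inflation rates plus wormhole jumps around the best
  universe, gated by WEP ramping 0.2 → 1 and a travelling-distance rate
  1 − t^{1/6}/t_max^{1/6}.

## Evaluation protocol

- External split: test size = round((1 − 0.8)·n) half-up, train the rest —
  260 samples give 208/52, 10661 give 8529/2132. Stratification allocates
  per-class test counts by largest remainder (within one sample of the
  class proportion) and errors if a class would be empty on either side.
- Internal validation: stratified 5-fold CV on the training partition; the
  reported aggregate is the **mean of per-fold metrics** (folds are also
  pooled for the held-out-prediction R²).
- Metrics, positive class = malignant: accuracy, sensitivity TP/(TP+FN),
  specificity TN/(TN+FP), precision TP/(TP+FP), RMSE, R² = 1 − SS_res/SS_tot,
  and two F1 variants: `f1_paper` = harmonic mean of specificity and
  sensitivity (the formulation used alongside this selector family) and
  `f1_standard` = harmonic mean of precision and sensitivity. Both are
  always reported, labeled; zero denominators yield a defined 0 with a
  flag. (A ratio-difference variant of R² without squares sometimes seen
  in print is not a coefficient of determination; the standard form is
  used.)
- `run_experiment` repeats split → filter → swarm → classifier bank for r
  seeded runs (default 30) and aggregates mean/min/max per classifier and
  metric; it asserts that no external test index ever reaches a training
  stage. `compare_algorithms` runs the same protocol per optimizer and
  tabulates internal and external blocks side by side plus mean selected
  count and iterations-to-best.
- Classifier bank (evaluation instruments, delegated to scikit-learn, all
  seeded): linear SVM (C = 1), 5-NN, CART, Gaussian naive Bayes, AdaBoost
  (50 rounds), MLP (one hidden layer of 100); scale-sensitive models get a
  standardizer.
- `feature_percentage` prints the retained fraction as an integer when the
  percentage is within 0.35 of one, else with one decimal (4.33% → "4%",
  4.44% → "4.4%"), mirroring how such reduction tables are typeset.

## Synthetic data

`make_feature_dataset` plants: informative columns (per-class Gaussian
means ±effect/2, unit within-class sd — effect is the between-class shift
in sd units), redundant columns a·source + ε with a ~ U[0.5, 1.5] and
ε ~ N(0, 0.2²) by default, and independent N(0,1) noise columns;
rectification at 0 is applied last when `nonnegative` (the default),
mimicking post-ReLU activations and satisfying the chi-square domain. One
RNG stream is consumed in a fixed order (informative block, slopes, source
assignment, redundant noise, noise block), so outputs are bit-identical per
seed. Defaults (200 samples, 10 informative + 20 redundant + 170 noise,
effect 2.0, balanced classes) describe a moderately hard problem in which
single features are weak (one 2-sd feature alone has Bayes accuracy
≈ 84%) but small subsets are strong.

What it does **not** emulate: feature correlations beyond pairwise linear
redundancy, heavy-tailed activation statistics, staining/optics variation,
patient-level structure, or class imbalance beyond the `class_balance`
knob. Passing tests show the machinery is correct and recovers planted
signal under these idealized conditions — not that any particular accuracy
will transfer to real blood-smear data.

`make_toy_cell_images` draws smooth filled discs (benign-like) vs
harmonically perturbed discs with punched cavities (blast-like) so the
image front end can run end to end; circularity 4π·area/perimeter² is
provably higher for the smooth class.

The image front end resizes to 224×224×3 in [0,1] (grayscale replicated)
and flattens the (7, 7, 512) feature map row-major over (row, col,
channel). The default backbone is a weight-free random-filter network
(fixed-seed 3×3 convolutions, ReLU, block pooling, fixed random 1×1
projection to 512 channels) — a deterministic stand-in exercising the full
contract without pretrained weights or network access; a real VGG19 adapter
slot raises an actionable error when the optional deep-learning dependency
is missing.

## Numerical and design choices

- All tie-breaks are by ascending feature index (top-k selection, RFE
  elimination, binarization fallback), making every stage deterministic.
- Elitist best-ever food source (strict improvement only). The alternative
  — re-deriving F from the current population — would break history
  monotonicity; it was rejected for that reason.
- RNG discipline: one `numpy` Generator per `fit`, seeded from
  `random_state`; the leader draws c₂ and c₃ as per-dimension vectors in
  that order. The internal CV fold seed is derived from the same
  `random_state`, so a run is one reproducible unit.
- Test and acceptance problem sizes were chosen so the planted structure is
  recoverable yet runs stay light: recovery studies use 200 × 200 matrices
  (10 agents × 30 iterations, seeds 1–5); the end-to-end protocol check
  uses 120 × 60 with 5 runs × 20 iterations and a reduced comparison. The
  recovery study plants 10 informative among 190 noise columns: planted
  *redundant* copies carry the same class signal as their sources, so a
  wrapper that swaps a copy for its source behaves correctly yet would
  score as a miss — informative-recovery is only a meaningful yardstick
  without planted redundancy.
- The swarm can search the full feature space (`search_space="full"`) or
  the filtered pool (default `"candidate"`); with strong pre-filters the
  pool is small and signal-enriched, which is the statistically enhanced
  configuration.

## Known limitations

- The wrapper fitness saturates on easy problems (many subsets reach CV
  accuracy ≈ 1), after which the search cannot distinguish them and keeps
  the first best found; selected subsets are then one of many equivalent
  optima rather than the planted set exactly.
- Chi-square on value sums assumes non-negative inputs; matrices with
  negative values must be rectified or shifted first (the generator's
  `nonnegative` default does this).
- The GA ignores `binarize_threshold`/`lb`/`ub` (it is natively binary).
- No significance testing between optimizers is provided; the comparison
  reports means over seeded runs only.
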