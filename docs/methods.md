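# Methods

## Problem setting

The package targets the "large m, small n" regime: a nonnegative feature
matrix V (m features × n samples) with a class label per sample, where m is
in the thousands (gene families, microarray probes) and n below a couple of
hundred (species, patients). Direct per-feature ranking is noisy and blind
to feature redundancy; the combined selector first compresses V into r ≪ m
nonnegative parts and ranks the parts, then distributes part relevance back
to features.

## NMF by multiplicative updates

`nmf_factorize` minimizes the squared Frobenius error ‖V − WH‖²_F under
W, H ≥ 0 with the classic multiplicative rules, W updated first and H
against the updated W within each sweep. Numerical choices:

* **Initialization** — W, H ~ Uniform(0.1, 1.1) from the given seed.
  Strictly positive entries avoid the absorbing zeros of the multiplicative
  flow; an explicit `init=(W0, H0)` overrides the seeded draw.
* **Division guard** — ε = 1e-12 added to each denominator. At the data
  scales involved (entries O(1)–O(10²)) this perturbs iterates far below
  the convergence tolerance.
* **Stopping** — after each sweep the non-squared error ‖V − WH‖_F is
  recorded; iteration stops at `max_iter` (default 500) or when the
  relative per-sweep decrease falls below `tol` (default 1e-6). `tol=0`
  forces exactly `max_iter` sweeps, which is what the reference-equivalence
  tests use.
* **Monotonicity** — the objective history is non-increasing; tests allow
  +1e-10 slack for floating-point noise.
* **Scale covariance** — scaling V by c > 0 and both starting factors by
  √c scales every objective iterate by exactly c; this is the form of the
  scale-equivalence property that is an identity of the update algebra
  (with a shared unscaled initialization it holds only asymptotically).
* **Initialization sensitivity** — multiplicative updates have a sublinear
  tail and, from an unlucky start, can need thousands of sweeps to push an
  exactly factorizable residual below 1e-6 (measured: 10–15% of random
  8×6 instances at ranks 2–3 stall between 1e-4 and 1e-2 after 500 sweeps,
  then keep descending to 1e-12 given 5000). Where near-exact recovery
  matters, run a handful of seeded restarts and keep the best — the
  exact-factorization tests do exactly that (5 restarts, each capped at
  500 sweeps).
* **Rank** — there is no principled default for r in this design; the
  selector uses min(50, min(m, n) − 1) when the caller gives none, keeping
  r below the sample count so H rows remain estimable sample encodings.

## ReliefF

`relieff_weights` implements the canonical multiclass form: min–max
normalized features, Manhattan instance distance, k nearest hits, k nearest
misses per contrasting class weighted by P(c)/(1 − P(y)), weights averaged
over sampled instances so each lies in [−1, 1].

* **Sampling** — default is full deterministic sampling (every instance
  once); an integer `n_iterations` samples without replacement per pass.
  Full sampling makes the weights an exact, permutation-invariant function
  of the data, which is what the brute-force equivalence tests check.
* **k** — default 10, capped (with a warning) at the smallest class size
  minus one so every instance has k hits; a class of size 1 is an error.
* **Ties** — neighbor ties at equal distance are included by ascending
  sample index; feature-rank ties by ascending feature index. Both rules
  exist purely for determinism.
* **Degeneracies** — a constant feature has zero range, zero diff, and
  hence weight exactly 0 (it also contributes nothing to distances).
* **Duplication caveat** — duplicating every sample with k doubled does
  *not* preserve weights: each instance's duplicate sits at distance 0 and
  fills a hit slot, exactly halving the hit term (w_dup = −H/2 + M).
  Strong features keep their ranks; near-zero features can swap. The test
  suite asserts the exact halving relation rather than a false invariance.

## The combined selector

`nmf_relieff_select` factorizes V, scores H's rows with ReliefF, and in
gene mode back-maps with score(f) = Σ_j max(w_j, 0)·W[f,j]/‖W[·,j]‖₁.
Design choices that were genuinely open:

* **Back-mapping** — components with negative ReliefF weight are clamped
  to zero rather than subtracted: a class-irrelevant metagene should not
  punish the features it happens to share with a relevant one. Normalizing
  each basis column to unit L1 mass makes the gene scores a partition of
  the total positive component weight (they are nonnegative and sum to
  Σ_j max(w_j, 0)), so scores are comparable across ranks.
* **Both output modes** are exposed; neither is privileged. Component mode
  cannot be used inside cross-validation (a held-out sample has no H
  column), so the CV harness requires gene mode for this selector.
* **PCA-ReliefF** mirrors the construction with centered PCA scores;
  components are sign-fixed (largest-magnitude loading positive) for
  determinism.
* **SVM-RFE** retrains a linear SVM (C = 1) and drops the `step` smallest
  squared-weight features per round; the optional mRMR pre-filter ranks
  features by mutual-information relevance minus mean pairwise redundancy
  on 3 equal-frequency bins and discards the bottom half before RFE.
  Binary labels only, matching its benchmark role.

## Evaluation harness

Stratified 5-fold CV, repeats re-shuffled with seed + repeat index. With a
`SelectorSpec` the selection step is re-fit inside every training fold;
passing a pre-computed `SelectionResult` instead reproduces the laxer
select-once-outside-CV protocol for comparison. Per-fold scaling (min–max,
fit on the training fold) precedes the classifier: linear SVM (C = 1,
margin as AUC score), random forest (500 trees, class-probability score) or
kNN (k = 5, vote-fraction score).

Metrics come in two conventions. `standard` is SEN = TP/(TP+FN),
SPE = TN/(TN+FP). `as_printed` computes SEN = TP/(TP+FP) and
SPE = TP/(TP+FN) — formulas that circulate in parts of the applied
literature and that equal precision and recall of the positive class; the
two conventions agree whenever FP = FN, and every report records which was
used. AUC is always the pairwise concordance count with half credit for
ties, an exact, tie-robust equivalent of the trapezoidal ROC area.

## Synthetic data

`simulate` draws features i.i.d. given the class: baseline mean 5 for all
background features, and for the planted set in class 1 a mean raised by
`effect_size` × the model's noise sd at that mean. Models: Poisson
(sd √5 ≈ 2.24), negative binomial with dispersion 0.5 so var = μ + 0.5μ²
(sd ≈ 4.18 — the overdispersion typical of gene-family copy counts), and
zero-clipped Gaussian with sd 1 (microarray-like intensities). Defaults
(1000 features, 100 samples, 10 informative, effect 3, negative binomial,
balanced classes) define the regime the recovery statistics are quoted in.

What the generator deliberately omits: correlation among background
features, phylogenetic structure among samples, batch effects, and
heavy-tailed per-feature baselines. Recovery and leakage results on this
generator therefore certify the algorithmic machinery (a selector that
fails here is broken) but do not predict absolute performance on real
gene-family or microarray data, where redundancy and structure can help or
hurt each selector differently.

## Problem sizes used in the checks

The recovery statistic runs 15 generator seeds at 1000 × 100; the NMF
reference-equivalence check uses 100 random matrices up to 50 × 50 at 60
sweeps; the leakage guard uses 100 × 40 pure-noise data with 15 CV repeats;
the acceptance script's benchmark and sweep use 500 × 80 and 300 × 60
matrices with 3 repeats. These sizes were chosen to make every statistic
stable to reruns while keeping a full run in well under a minute of compute
per component.

## Known limitations

* Multiplicative-update NMF is the slowest of the standard NMF solvers;
  for production-scale matrices (m ≫ 10⁴) an alternating-least-squares
  backend would be preferable, but the update rule here is the point of
  the package.
* ReliefF's O(n²m) distance computation is fine for n ≤ a few hundred
  (the intended regime) and quadratic beyond it.
* The evaluation harness is binary-only, matching the benchmarks it
  reproduces; ReliefF itself is multiclass-ready.
* `select_longest_isoform` trusts the GFF3 `Parent` links and takes
  transcript length from the supplied FASTA when present, else spliced
  exon length, else genomic span; unparented mRNAs are skipped with a
  warning rather than guessed at.
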