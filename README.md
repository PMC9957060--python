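# nmfrelieff

Feature selection for high-dimensional, small-sample nonnegative matrices —
gene-family copy-number tables and microarray expression data — built around
the combination of nonnegative matrix factorization (NMF) and ReliefF
instance-based feature weighting, with the standard baselines (plain ReliefF,
PCA-ReliefF, SVM-RFE with an optional mRMR pre-filter) and a leakage-safe
cross-validated benchmarking harness.

The intended user is a comparative genomicist or machine-learning
bioinformatician who has a features × samples matrix with class labels (e.g.
gene-family counts per insect species labeled herbivorous/non-herbivorous, or
probe intensities per tumor sample) and wants a short, class-informative
feature list plus honest cross-validated performance numbers for it.

## The method

Given a nonnegative data matrix **V** ∈ ℝ≥0^(m×n) (m features, n samples),
NMF seeks nonnegative **W** (m×r) and **H** (r×n) minimizing

    min ‖V − WH‖²_F   s.t.  W ≥ 0, H ≥ 0

by the multiplicative updates

    W ← W ⊙ (VHᵀ) ⊘ (WHHᵀ),    H ← H ⊙ (WᵀV) ⊘ (WᵀWH)

(⊙, ⊘ element-wise), which keep the factors nonnegative and make the
Frobenius objective non-increasing. Columns of W are *metagenes*; row j of H
is the encoding of every sample on metagene j.

ReliefF then scores each of the r metagene encodings by its ability to
separate near misses (nearest neighbors of other classes) without separating
near hits (nearest neighbors of the same class): for a sampled instance x of
class y, feature f's weight is updated by

    w_f += − mean_{h ∈ kNN hits} diff(f,x,h)
           + Σ_{c≠y} P(c)/(1−P(y)) · mean_{m ∈ kNN misses of c} diff(f,x,m)

with range-normalized diffs and empirical class priors P(·). In *gene* mode
the positive component weights are mapped back to the original features,

    score(f) = Σ_j max(w_j, 0) · W[f,j] / ‖W[·,j]‖₁ ,

so the selector outputs named features (gene families); *component* mode
returns the metagene indices themselves.

Classifier evaluation is stratified 5-fold cross-validation (repeatable, with
selection re-fit inside every training fold by default) reporting ACC,
SEN, SPE and the pairwise-concordance AUC

    AUC = (#{score_pos > score_neg} + ½·#ties) / (positiveNum · negativeNum).

Upstream of all of that, `nmfrelieff.genefam` builds the species × gene-family
count matrix itself: scaffold-N50 assembly filtering (default: drop < 400 kb),
longest-isoform selection from GFF3/FASTA, and tabulation of gene→family
assignment tables.

## Worked example

Generate an 80-sample, 500-feature negative-binomial count matrix with 10
planted informative features (class mean shifted by 3 noise-sd), select 10
features with NMF-ReliefF, and benchmark them:

```sh
$ nmfrelieff simulate --n-features 500 --n-samples 80 --n-informative 10 \
      --effect-size 3 --seed 7 --out matrix.tsv
INFO nmfrelieff: wrote 500x80 matrix (10 planted) to matrix.tsv

$ nmfrelieff select --method nmf-relieff --in matrix.tsv --out selected.tsv \
      --n-select 10 --rank 20 --seed 7
INFO nmfrelieff: nmf-relieff selected 10 features -> selected.tsv

$ head -6 selected.tsv
rank	feature_id	score
1	f384	0.00413018021
2	f27	0.003922808092
3	f443	0.003711846209
4	f463	0.002913732512
5	f112	0.002905759357
```

The scores are each feature's share of the positive ReliefF weight of the
metagenes it loads on; here the ten selected features are exactly the ten
planted ones (`matrix.tsv.planted.txt` lists indices 27 112 150 286 307 337
384 414 443 463). Cross-validating the full pipeline — selection re-fit
inside each of 5 folds, linear SVM, 3 repeats —

```sh
$ nmfrelieff evaluate --in matrix.tsv --out report.json --method nmf-relieff \
      --n-select 10 --rank 20 --repeats 3 --seed 7
INFO nmfrelieff: ACC=1.000 SEN=1.000 SPE=1.000 AUC=1.000
```

reports perfect held-out classification at this effect size: every fold's
accuracy, sensitivity, specificity and AUC are 1.0 (`report.json` holds the
per-fold confusion counts; `report.json.summary.tsv` the means ± standard
errors). At effect 0 the same pipeline stays at chance (AUC ≈ 0.5) — the
selection-inside-folds protocol does not leak.

The `sweep` subcommand runs the full grid (four selectors × feature counts
{5,10,20,30,40,50} × classifiers, 15 repeats by default), and `build-matrix`
turns gene→family assignment tables into the count matrix. Every command
writes a `.provenance.json` with parameters, seed and input checksums.

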