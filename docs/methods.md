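# Methods

## Problem setting

The package targets rare-disease case detection in a phenotyped patient
pool with severe class imbalance: on the order of 30 cases against ~7,000
controls (prevalence ≈ 0.4%), where both classes share a broad background
of symptoms (here, kidney-related phenotypes) and the disease signal lies
in a modest set of disease-spectrum concepts and their ontology
descendants. All stages assume only (a) a DAG-shaped phenotype ontology,
(b) per-patient sets of distinct ontology terms, and (c) case/control
labels.

## Information content and similarities

Information content is structural, not corpus-based: IC(p) = −log(n_p/N)
with n_p the number of terms p subsumes *including itself* and N the total
term count of the loaded ontology. Counting the term itself keeps IC finite
at leaves (otherwise a leaf would have −log 0); the natural logarithm is
the default, and since Lin similarity is a ratio of ICs it is invariant to
the base (a property the tests check to 1e−12). Both choices are exposed
as parameters.

Lin similarity is 2·IC(MICA)/(IC(p₁)+IC(p₂)). Conventions at the edges of
the formula: sim(p, p) = 1 always, including the root where the ratio is
0/0 — a patient's own phenotype must register as fully present; when the
denominator is 0 for distinct terms (both terms at IC 0) the similarity is
0. MICA ties on IC are broken by term id for determinism; only the IC value
reaches downstream code, and it is unique.

The restricted hierarchical similarity interprets "same branch" as
reflexive subsumption: the value equals Lin's iff one term is an ancestor
of the other, else 0. This is the package's central modelling element: two
ontological siblings (chronic kidney disease vs acute kidney injury) have
an informative common parent and hence a substantial Lin similarity, but no
subsumption relation and hence a null restricted similarity — which is what
prevents generic renal patients from looking like ciliopathy cases.

Embedding cosine similarity consumes a precomputed term-vector table
(word2vec text format). The raw cosine in [−1, 1] is reported by the
pairwise operation; for vectorization negatives are clipped to 0 so that
every method produces features on a common [0, 1] scale.

## Patient representation

The feature space P is the lexicographically sorted set of distinct terms
in the dataset; by default it is built from the full dataset (the term
vocabulary is not label information, and the study design defines P over
all patients), with a train-only scope available to rule out vocabulary
leakage in stricter analyses. Each patient's vector is
V[i] = max_{d∈D} sim(p_i, d), computed as a column-max over a precomputed
|P|×|P| similarity matrix; under the binary similarity this reduces to the
presence/absence indicator. Patient terms outside P are ignored in the max.

Cohort inclusion mirrors a transplant-censored EHR design: phenotypes dated
on/after a patient's censor date are removed, and — conservatively —
undated phenotypes are removed too when a censor date exists; patients then
need at least 4 distinct resolvable terms to stay in the cohort. Terms the
ontology cannot resolve are dropped with a logged warning rather than
raised, since real extractions are noisy.

## Classification protocol

Defaults: 10 repetitions of a stratified holdout with test fraction 0.33.
The fraction is 0.33 rather than exactly 1/3 because the reference cohort
counts (20/4,844 train and 10/2,387 test out of 30/7,231) correspond to a
0.33 stratified holdout; `make_splits` reproduces that partition exactly.
Repeat r uses seed master_seed + r.

Within each training set, hyperparameters are chosen by 5-fold stratified
cross-validation. Inside every fold, in order: (1) feature selection — a
200-tree random forest is fit on the fold's training part and features with
impurity importance ≥ the mean importance are kept (degenerate
all-below-mean cases fall back to the single best feature, with a warning);
(2) undersampling — the majority-class (control) vectors are replaced by
the k-means centroids of their points with k equal to the number of
minority (case) samples, 10 restarts, 300 iterations, seeded. Validation
parts and the test set are never undersampled. Centroid coordinates are
fractional even for binary inputs: a centroid is a prototype control, not
an observed one. The model-selection metric is mean average precision,
chosen because at 0.4% prevalence precision-recall behaviour is the
quantity of interest; the winning combination (ties → first in grid order)
is refit on the whole training set with freshly fit selection and
undersampling.

Classifier grids (configurable): ridge α ∈ {0.01, 0.1, 1, 10}; RBF-SVM
C ∈ {0.1, 1, 10} with the variance-scale kernel-width heuristic ×
{0.5, 1, 2}; random forest 200 trees, depth {None, 10}, min leaf {1, 5};
XGBoost 200 trees, depth {3, 6}, learning rate {0.05, 0.1}. Scores are
native class probabilities where the family provides them (RF, XGBoost)
and a logistic squash of the decision margin otherwise (ridge, SVM); all
evaluation metrics are rank-based or threshold-calibrated, so only the
ordering matters, and monotone-transform invariance is tested explicitly.

## Evaluation

The decision threshold is the smallest observed control score t such that
the fraction of controls strictly above t is at most 1 − target (target
specificity 0.90 by default); positives are scores > t, so the achieved
specificity is ≥ the target and, with n controls, within 1/n of it.
Calibration uses the test-set control scores — the operating point is a
presentation device to compare methods at a common specificity — and a
train-calibrated variant is available through the same function. An
epsilon (1e−9) in the count comparison guards against (1−target)·n landing
just below an integer in floating point.

Top-k metrics use m = max(1, round(k/100 · n)); ranking ties are broken by
score descending then patient id ascending, so reports are reproducible.
AUROC is the Mann–Whitney statistic (ties count ½) and AUPRC is step-wise
average precision, both delegated to scikit-learn and cross-checked in the
tests against independent pairwise-count and threshold-group oracles. Note
that the finite-sample average-precision estimator of a label-independent
ranker sits slightly *above* the prevalence — an O(log n/n) harmonic bias
that is visible with 30 cases (≈0.0053 vs 0.0041) and vanishes as the case
count grows; the acceptance machinery reports both the analytic baseline
and the Monte-Carlo mean.

Aggregation over the R repetitions reports the mean and a 95% t-interval,
mean ± t₀.₉₇₅,R−1·sd/√R, truncated to [0, 1] for rate metrics.

## Synthetic data generator

The generator emulates the study structure, not any particular dataset.
Ontologies are random DAGs grown level by level: each non-root term takes
one parent from the previous level plus, with probability 0.1 by default, a
second parent among earlier terms (multiple inheritance; earlier-only
parents guarantee acyclicity). Cohorts default to 30 cases / 7,231 controls.
Five signature terms model the disease spectrum; they are drawn from
mid-sized concept families (between 3 descendants and ~10% of the ontology;
the cap relaxes automatically on small ontologies). Each patient carries
each signature term with its class's carriage probability — cases 0.8,
controls 0.05 by default — expressed as a uniformly chosen reflexive
descendant, modelling variable coding granularity; this descendant coding
is precisely what separates restricted-Lin vectors from binary vectors.
Remaining phenotypes are drawn from a background region shared by both
classes. The default background excludes the signature subtrees so that the
carriage probabilities are the *only* channel for signature-branch terms;
without this exclusion, uniform background sampling would hand controls
signature terms at a rate far above the nominal 5% and the carriage
parameters would lose their meaning. Per-class distinct-term counts follow
a lognormal whose two parameters are solved from a target median and IQR
(defaults: cases 18 (10.3–35.8), controls 10 (6–18)); the fit preserves the
median and the IQR ratio — a two-parameter family cannot also match both
quartile locations of an asymmetric target, and the median is what the
recovery tests check. Synthetic embeddings follow the ontology as a
Gaussian random walk (child = mean of parents + N(0, 0.5²I), root standard
normal), so cosine similarity decays with graph distance.

What the generator does *not* emulate: extraction noise and negation errors
of NLP phenotyping, per-patient correlation between related background
phenotypes, age/sex structure, and real HPO scale (~15k terms; simulations
use 200). Passing recovery tests therefore show that the pipeline detects a
subsumption-structured enrichment signal at realistic imbalance — not that
it would achieve any particular performance on hospital EHR data.

## Problem sizes in the checks

The end-to-end recovery check runs the full pipeline (restricted Lin +
random forest, default grids) on five simulated cohorts of 200 terms and
30 cases / 3,000 controls (carriage 0.8/0.05), three repetitions per
cohort, and requires mean sensitivity ≥ 0.8 at 90% specificity; the null
check uses five cohorts of 30 / 800 with identical case/control generative
parameters and requires mean AUROC in [0.4, 0.6]. Monte-Carlo baselines use
the study-scale 30/7,231 label vector. These sizes keep a full run in the
low minutes on a single CPU while leaving the class imbalance and signal
structure intact.

## Known limitations

- Structural IC ignores term frequency in a corpus; rare-but-shallow terms
  get modest IC.
- Cluster-centroid undersampling produces dense prototype vectors from
  sparse patient vectors; with few cases and weakly informative features a
  classifier can learn "dense smooth = control" and rank sparse test
  controls too high. The repeated-split protocol averages over this
  instability, but single splits can be poor (this is visible in one of the
  five recovery seeds).
- Threshold calibration on test controls gives the presentation operating
  point, not a deployable threshold; use the train-calibrated variant for
  prospective use.
- The CLI's `run` command rebuilds the feature space from the full cohort
  (see above); per-repetition feature *selection* is still train-only.
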