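# Methods

This note documents the models and procedures implemented in `dictox`,
the parameter choices that matter, and what the synthetic studies do and
do not establish.

## Chemical standardization

Each SMILES is passed through a cycle of RDKit standardization steps —
cleanup, largest-organic-fragment selection (salt stripping),
charge neutralization, tautomer canonicalization — iterated until the
canonical SMILES of consecutive iterations is string-equal (the fixed
point), with a default budget of 5 iterations. On non-convergence the
most frequent SMILES across iterations is chosen, ties broken by taking
the lexicographically smallest, so the output is always deterministic.

Protonation at pH 7.4 is applied **once, after** the loop, because the
neutralization step would undo it. The ionization engine is a SMARTS +
pKa rule table using textbook group values: sulfonic (−1), sulfinic and
phosphonic (≈2), carboxylic acids (4.8) and tetrazoles (4.9) are
deprotonated at 7.4; guanidines (≈13), amidines (≈11) and aliphatic
amines (≈10.5) are protonated; phenols (≈10), thiols (≈10.5), anilines
(≈4.6), pyridines (≈5.2) and imidazoles (≈7.0) stay neutral. Each atom
is modified at most once (strongest rule first), yielding a single
deterministic protomer rather than an enumeration. This is a coarse
model: it ignores substituent effects on pKa and multiprotic coupling,
which is acceptable here because the ionized form feeds fingerprints and
descriptors, not quantitative pKa claims.

The match key for all cross-dataset joins is the standard InChI of the
standardized, pH-adjusted structure. Stereochemistry is retained
(canonical isomeric SMILES); matching is therefore stereo-sensitive, and
datasets curated with stereo-insensitive keys may join slightly
differently.

## Label assembly

Concern categories binarize as most/less → 1, no → 0; ambiguous
compounds are excluded from classification (they can still be scored by
`predict_unlabeled`). Duplicate records collapse toxic-wins (label =
max), with the representative SMILES the first by sort order and the
most severe concern kept so label and concern stay consistent.
Enrichment with a second binary-labeled source adds only compounds
absent from the primary set, filtered by mode (toxic-only,
nontoxic-only, all); on overlapping keys the primary label always wins.
Contributed compounds get concern `unknown` since binary sources carry
no concern grades. Concordance between sources is percent agreement on
shared keys plus the F1 of the secondary labels treated as predictions
of the primary ones.

## Feature spaces

* **Structure**: 2048-bit Morgan fingerprints, radius 2. This
  fingerprint is also the similarity basis for v-NN imputation and the
  applicability domain.
* **Physicochemical**: the RDKit 2-D descriptor set (~210 descriptors).
  Columns that fail to compute on any compound are dropped dataset-wide;
  residual infinities are clipped to the column's finite extremes — a
  deterministic rule that keeps the matrix finite without imputing
  values outside the observed range.
* **Annotations**: one-hot encoding over the sorted vocabulary, absence
  = 0, followed by a population-variance filter at 0.001 (a binary
  column survives if its positive rate is roughly outside [0.001, 0.999]).
* **Cmax**: stored in micromolar; for modeling, log10 values are the
  intended transform, matching pharmacological convention for exposure
  data spanning orders of magnitude.
* **Omics profiles**: replicate profiles are aggregated by elementwise
  median per compound. Missing profiles are imputed by **v-NN**: the
  elementwise median over all library compounds with a profile and
  Tanimoto similarity strictly greater than 0.70; compounds on the
  exclusion list (the held-out test set) never contribute, and a query
  with no qualifying neighbor is dropped rather than imputed. Unlike
  k-NN the neighbor count varies per query; each imputed feature lies
  within the range of its contributing neighbors by construction.

## Association statistics

Feature–label association uses the test matched to the data type:
chi-squared (Pearson, no continuity correction) on the contingency table
for categorical features; Kruskal–Wallis with tie correction across the
three concern groups for continuous features; two-sided Mann–Whitney U
for binary or pairwise contrasts, exact when both samples have ≤ 8
observations and tie-free, mid-rank normal approximation otherwise.
Bonferroni correction applies over the number of pairwise contrasts
(3 for most/less/no pairs); multiplicity across *features* is reported
but not corrected, so rankings are by raw p-value with name tie-breaks.
Column type is inferred as categorical when a column has ≤ 2 unique
finite values, continuous otherwise; constant columns are skipped with a
log message. Under null synthetic data the per-feature false-positive
rate at α = 0.05 is calibrated (checked over 1000 replicates in the
acceptance suite), which also means that in a matrix of N null features
about 0.05·N will reach p < 0.05 — feature-level multiplicity is the
caller's responsibility.

## Structural alerts

Fragments are generated by recursive cleavage of acyclic single
(non-aromatic, non-ring) bonds with rings kept intact; every connected
piece between 2 and 18 heavy atoms is a candidate, expressed as
canonical SMILES and matched as a substructure query. This construction
guarantees each fragment matches its parent, and it equals an exhaustive
enumeration of connected atom subsets whose boundary consists solely of
cuttable bonds — the independent oracle used in the tests. Open valences
are implicit (a fragment's unsubstituted positions match any
substitution), so mined patterns generalize across decorations.

Mining pools fragments from either all compounds or only toxic ones,
then counts per-compound occurrences over the *full* dataset (a compound
either contains a pattern or not), keeps patterns occurring ≥ 5 times,
and scores PPV = toxic occurrences / occurrences. The two settings are
merged by pattern union (higher-occurrence record wins), and filters
remove PPV < 0.5, fragments of ≤ 4 atoms, and a blocklist of generic
scaffolds (benzene by default). A reporting view restricts to
occurrences > 10 and PPV > 0.6. Occurrence counting is accelerated by a
packed pattern-fingerprint prescreen with exact substructure
verification of the survivors. The `most_concern` labeling scheme
contrasts most- vs no-concern compounds with less-concern excluded from
the counting base.

## Modeling

One random-forest classifier per feature space. Hyperparameters come
from a successive-halving random search over a fixed grid — trees
{100, 300, 500}, depth {unlimited, 10, 20}, minimum split {2, 5, 10},
feature rule {sqrt, log2} — with 8 candidates sampled by the run seed,
halving ratio 3, and the training-subset size as the resource, each rung
scored by mean validation AUC-ROC under stratified 5-fold CV. The
minority class is randomly oversampled with replacement **inside each
training fold only**; validation folds are never resampled, so fold
scores are leak-free.

The winning configuration is refit per fold to produce out-of-fold
probabilities for every training compound. The decision threshold
maximizes Youden's J = TPR − FPR over all distinct out-of-fold scores as
candidate cuts (predict positive at score ≥ cut). J values are compared
exactly via the integer form TP·n_neg − FP·n_pos to avoid
floating-point artifacts in ties; genuine ties resolve toward the
largest cut (the more specific classifier). The final model is refit on
the full oversampled training data, and the frozen threshold is used for
all later predictions.

Evaluation reports balanced accuracy, sensitivity, specificity, F1 and
MCC at the threshold plus AUC-ROC and AUCPR (average precision). For an
uninformative (constant-score) classifier AUCPR equals the positive
prevalence and AUC-ROC equals 0.5 — the baselines against which model
lift is judged; under a 65-positive/25-negative test composition the
baseline AUCPR is 0.72, under 57/21 it is 0.73.

Ensembles soft-vote over probabilities rescaled so each model's own
threshold maps to 0.5 (piecewise linear: s = 0.5·p/t below the
threshold, 0.5 + 0.5·(p−t)/(1−t) above); the ensemble predicts toxic at
mean rescaled score ≥ 0.5. A single-model ensemble therefore reproduces
that model's thresholded predictions exactly.

The applicability domain assigns each test compound the maximum Tanimoto
similarity to any *same-label* training compound and bins it into
[0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0]; balanced
accuracy and AUCPR are reported per bin, AUCPR as NA in single-class
bins.

## Synthetic studies

The generator emulates the statistical structure of the real study: a
1020-compound dataset with concern proportions 299 : 443 : 278
(most : less : no); a planted nitro-aromatic toxicophore (9 heavy atoms,
so it survives the small-fragment filter) carried by toxic compounds
with probability 0.95 and by nontoxic ones with probability 0.05 (5 %
label noise); lognormal Cmax with a 1 log10-unit class shift (toxic
log-mean 0.5, nontoxic −0.5, SD 1.0, micromolar); 20 annotation terms at
base rate 0.10 with 4-fold odds enrichment of three "mechanism" terms
among toxic compounds; 100 Gaussian omics features of which 10 carry a
one-SD mean shift in toxic compounds; and 20 % of compounds lacking an
omics profile (v-NN imputation targets). Molecules are assembled from a
fixed ~40-piece vocabulary of valid SMILES building blocks, which gives
fragment mining realistic combinatorics; all outputs pass
standardization and have unique match keys.

What passing on synthetic data shows: the machinery recovers planted
structure at the stated noise levels — alert mining finds the
toxicophore at PPV ≈ 1, association ranking puts the informative
features on top, structure models beat the prevalence AUCPR baseline by
over 0.15 out of fold. What it does not show: performance on real
pharmaceuticals, whose structural diversity, label noise sources,
assay batch effects and feature correlations the generator does not
emulate. In particular the toxicophore signal here is far cleaner than
any real cardiotoxicity pharmacophore.

## Pipeline

`run_pipeline` executes standardize → assemble → featurize → stats →
alerts → train → evaluate → ensemble → applicability-domain from one
validated config, writing per-stage CSV outputs and a manifest with
input hashes, per-stage record counts, output hashes, model thresholds
and the leak audit. The held-out test split (stratified, 10 % per class
by default) is fixed immediately after assembly; test keys are excluded
from v-NN neighbor pools and from alert mining, thresholds derive from
out-of-fold training scores only, and the manifest contains no
timestamps, so a rerun with the same seed and inputs is bit-identical.
Any stage failure aborts the run with the stage named.

## Sizes and numerical choices

Default test-suite and acceptance problem sizes are chosen as the
smallest that exercise the claims: unit fixtures of tens of compounds,
statistical calibration at 1000 replicates × n = 150, parameter recovery
on the full default study (n = 1020, five seeds), pipeline integrity at
n = 300. Ties and degenerate inputs are handled deterministically
throughout: constant association features are skipped, constant scores
return a degenerate threshold with a warning, all-zero fingerprints have
Tanimoto 0 by definition, single-class evaluations report NA ranking
metrics, and every stochastic step routes through a seeded generator.

## Known limitations

* The pKa rule table covers common ionizable groups only; exotic or
  strongly coupled sites fall back to the neutral form.
* The physicochemical space is the RDKit 2-D descriptor set; no 3-D
  descriptors are computed.
* Fragmentation never opens rings, so purely ring-internal toxicophores
  are only found as whole rings or ring+substituent patterns.
* The halving search samples 8 of 54 grid points by default; it is a
  budgeted search, not an exhaustive optimum.
* Alert PPV is not corrected for multiple testing across the mined
  fragment pool; it is a descriptive screening statistic.
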