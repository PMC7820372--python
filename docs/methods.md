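# Methods

## Overview

`apopred` is a two-tier protein-family classifier. Tier 1 decides whether a
sequence is an apolipoprotein; tier 2 assigns tier-1 positives to one of
seven subfamily labels (ApoA–ApoE, ApoL, and Apoelse, the pooled class for
the small subfamilies ApoF/ApoH/ApoM/ApoN/ApoR). Each tier is a pipeline of
sequence encoding, ANOVA feature ranking with optional incremental feature
selection, and a standardised RBF-kernel SVM tuned by grid search. The
package follows scikit-learn estimator conventions throughout: encoders are
stateless transformers, `AnovaTopK` is a selector, `GridRBFSVC` a
classifier, and `make_tier_pipeline` composes them so that generic
cross-validation drivers refit the whole chain — including feature
selection — inside every training fold.

## Encoders

All four encoders assume the standard 20-letter alphabet (ambiguity codes
are rejected upstream) and are pure functions of (sequence, config).

**DPC.** Ordered adjacent pair frequencies, D(r,s) = N_rs/(L−1), 400
dimensions, summing to 1. Requires L ≥ 2.

**CKSAAP.** For each gap k = 0…k_max (default k_max = 5) the 400 ordered
pairs (a at i, b at i+k+1) are counted and divided by the number of
eligible positions N_total,k = L−(k+1). Each k block is normalised by its
own denominator and sums to 1; blocks are concatenated in increasing k.
Requires L ≥ k_max+2.

**188D.** 20 residue frequencies (alphabetical), then for each of eight
three-group physicochemical partitions of the alphabet (hydrophobicity,
van der Waals volume, polarity, polarizability, charge, secondary-structure
propensity, solvent accessibility, surface tension — the standard
composition/transition/distribution groupings, shipped as a versioned
table): 3 group compositions; 3 transition frequencies, counting unordered
cross-group adjacencies divided by L−1; and 15 distribution values — per
group, the 1-based position of occurrence number ⌈q·n_g⌉ for
q ∈ {0, .25, .5, .75, 1} (q = 0 meaning the first occurrence), divided by
L, with all five values 0 when the group is absent. 20 + 8·21 = 188.

**PseAAC.** Residue frequencies plus per-property sequence-order factors.
Each of nine physicochemical scales (hydrophobicity, hydrophilicity,
side-chain mass, pK1 of α-COOH, pK2 of α-NH3, pI at 25 °C, rigidity,
irreplaceability, flexibility) is standardised to zero mean and unit
variance over the 20 residues; tier j contributes
τ₍p,j₎ = (1/(L−j)) Σ h_p(Rᵢ)h_p(Rᵢ₊ⱼ). With Z = 1 + w·Στ, the vector is
[fᵢ/Z …, w·τ₍p,j₎/Z …], ordered tier-major/property-minor, dimension
20 + 9γ, summing to 1 by construction (τ values may be negative; a
vanishing Z, which would require w·Στ ≈ −1, raises an error — it does not
occur at the default w). Defaults: γ = 10, w = 0.05 (the conventional
pseudo-composition weight; it only balances the frequency block against
the correlation block, and results are insensitive to it within an order
of magnitude). The numeric property table is a versioned built-in compiled
from standard amino-acid index collections; alternative tables can be
registered under a new `property_table_id`. Different published
pseudo-composition variants differ in exactly which correlation form they
use; the per-property (series) form implemented here is the one consistent
with the 20 + 9γ dimensionality, and this choice is a documented
convention of this package rather than a claim about any external
implementation.

## Feature selection

Each feature is scored by the one-way ANOVA F statistic,
F = (SSB/(k−1))/(SSW/(n−k)) across label groups, computed by vectorised
two-pass group statistics. Conventions: a feature constant everywhere
(0/0) scores 0; zero within-group variance with non-zero between-group
variance scores +inf; ties in the descending sort keep original column
order. Preconditions: ≥ 2 classes, every class ≥ 2 samples.

Incremental feature selection sweeps subset sizes n = 1, 1+stride, … along
the ranking, scoring each by pooled stratified cross-validated accuracy of
a trainer (default: standardise + RBF-SVM with fixed C = 8 and the
data-scaled kernel width `gamma="scale"`; fixed hyperparameters keep the
sweep affordable, and a data-scaled width remains meaningful as the subset
dimension grows, which a single fixed grid midpoint would not). The
smallest n attaining the maximum accuracy wins, so a flat curve selects a
single feature.

One subtlety matters with thousands of candidate features: cross-validating
subsets of a ranking computed on *all* samples lets held-out folds
influence which features are scored, and on pure-noise data this inflates
the curve to near-perfect "accuracy". By default each fold therefore
re-ranks features on its training split and evaluates its own top-n
(`refit_ranking=True`); the reported `optimal_features` are the top-n of
the full-data ranking, which is the subset a final model refit on all data
would use. `refit_ranking=False` restores the classic fixed-ranking sweep
for comparison.

## Classification

`GridRBFSVC` standardises features (train-split mean/variance — RBF kernels
effectively require scaling, and the parameters are stored in the fitted
pipeline) and scans the grids C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and width
γ_RBF ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (standard libsvm practice) by pooled
stratified-CV accuracy, ascending, keeping the first strict improvement —
so ties resolve to the smallest C, then the smallest width. The winner is
refit on all data. Multiclass uses one-vs-one voting, the libsvm
convention. The fold count is clamped to the smallest class size when
necessary. Model files are a JSON envelope (encoder config, selected
features, hyperparameters, label set, provenance — enough to retrain
bit-compatibly from the same data and seed) plus an opaque joblib payload.

The two-tier predictor encodes each query with tier 1's encoder and
classifies; only positives are re-encoded with tier 2's encoder for
subfamily assignment. A per-record encoding failure (e.g. a sequence
shorter than an encoder's minimum) yields an error entry for that record
without aborting the batch.

## Evaluation

Binary metrics from pooled confusion counts: Sn = TP/(TP+FN),
Sp = TN/(TN+FP), Acc = (TP+TN)/N, and MCC with the convention that a zero
denominator factor gives MCC = 0. ROC curves sweep all distinct score
thresholds (tied scores give one vertex) and AUC is the trapezoidal area,
equal to the normalised Mann–Whitney U statistic. Cross-validation is
stratified with a recorded seed; metrics are pooled (micro-averaged) over
all held-out predictions rather than averaged over folds, matching how
confusion-count totals feed the formulas — at the problem sizes used here
the two differ negligibly, and the choice is recorded in the report.
Multiclass reports give overall accuracy, the pooled confusion matrix and
per-class sensitivity (class-wise recall, diagonal over row sum); overall
accuracy equals the count-weighted mean of per-class sensitivities, an
identity the tests assert numerically.

## Curation

Benchmark-style curation applies three steps: drop sequences containing
non-standard residues (B, J, O, U, X, Z) or shorter than `min_length`
(default 10; the encoders need L ≥ 2 and PseAAC L ≥ γ+1); reduce
redundancy at an identity cutoff (default 0.8); optionally pool small
subfamilies into Apoelse. Redundancy reduction is a transparent greedy
clustering, not a CD-HIT reimplementation: sequences are visited in
descending length (ties by id), each joins the first retained
representative with pairwise identity ≥ cutoff, else becomes a
representative. Identity = identical aligned positions under global
alignment (match 1, mismatch 0, linear gap −1, via Biopython's
PairwiseAligner) divided by the shorter sequence's length — the CD-HIT
convention. Exact cluster membership is not part of any reported quantity,
and a hook accepts an externally produced representative list (e.g. a real
CD-HIT run) instead. The procedure is idempotent, and every removed
sequence has identity ≥ cutoff to some retained representative.

## Synthetic data

The generator emulates labelled protein families: each class draws a
residue-frequency profile from a symmetric Dirichlet whose concentration
sets the compositional contrast (1.0 by default — strongly separated
profiles; large values approach uniform, making classes
indistinguishable), emits sequences i.i.d. from the profile with lengths
uniform in 60–140 (typical single-domain range, and comfortably above
every encoder minimum), then plants class-specific (a, b, k) pairs by
rewriting positions: each eligible start is overwritten with probability
`pair_signal_strength` (default 0.05 — against a ~1/400 background pair
rate this is a strong, recoverable signal). The default two-tier demo uses
7 subfamilies × 30 positives and 4 background families × 50 negatives,
mirroring the moderate class imbalance and heterogeneous negative class of
real plasma-protein benchmarks. Ground truth (profiles, planted pairs) is
returned with the data and written as JSON by the CLI.

What the generator does *not* model: phylogenetic relatedness, indels,
domain architecture, or homology between families. Passing tests therefore
demonstrate that the pipeline recovers compositional and k-spaced pair
signal correctly and without information leakage — not that any particular
accuracy will be attained on real UniProt-derived data, where the
discriminating signal is weaker and correlated with evolutionary history.

## Determinism and problem sizes

Every stochastic step (generator, fold assignment, grid-search CV) takes an
explicit seed, and seeded reruns produce byte-identical artifacts (JSON
keys sorted; TSV written deterministically). The bundled evaluation runs
use desk-scale sizes chosen to keep the full suite and the reproduction
script fast on a single CPU: the demo datasets above, top-100 feature
selection inside CV, a reduced 5×5 hyperparameter grid with 3 inner folds,
IFS sweeps capped at 40 features with stride 2, and 20 generator seeds for
the recovery measurement. The library defaults (full grids, stride 1,
uncapped IFS) are what a real benchmark study would use.

## Known limitations

- The greedy identity clustering is quadratic in dataset size; for
  thousands of sequences an external CD-HIT run fed through the
  representative-list hook is preferable.
- PseAAC values depend on the shipped property table; other
  pseudo-composition implementations with different tables or correlation
  forms will produce different (though similarly discriminative) vectors.
- ROC/AUC is reported for the binary tier only; the multiclass tier
  reports per-class sensitivity instead.
- No probability calibration; decision scores are SVM margins
  (one-vs-one vote tallies for multiclass).
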