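# Methods

This note documents the models and procedures implemented in `salivapred`,
the defaults chosen where the problem left the design open, and what the
synthetic fixtures do and do not demonstrate.

## Problem setting

The package addresses a binary prediction problem: given a human protein's
amino-acid sequence, decide whether it can move from blood circulation into
saliva. Proteins known to make this trip (validated in the literature) form
a small positive set; negatives cannot be observed directly and are
constructed by exclusion. Because the negative labels are weak, the package
supplements classification with a transductive ranking that only requires
trusted positives. Downstream, candidate disease biomarkers are triaged by
intersecting saliva-movable predictions with differentially expressed genes
and blood-secretory proteins.

## Sequence descriptors

Each protein is encoded as a 1,302-element vector. The blocks and their
dimensions:

| block | dim | notes |
|---|---|---|
| amino-acid composition | 20 | fractions, sum to 1 |
| dipeptide composition | 400 | adjacent ordered pairs / (L−1) |
| autocorrelation | 720 | 3 methods × 8 scales × lags 1–30 |
| CTD | 147 | 7 groupings × (3 comp + 3 trans + 15 dist) |
| physicochemical summary | 8 | means, charge, pI, MW, length |
| disorder profile | 2 | mean fold index, disordered fraction |
| secondary-structure content | 3 | Chou–Fasman argmax per residue |
| radius of gyration | 1 | 2.2·L^0.38 |
| TAT motif | 1 | boolean |

Autocorrelation uses property scales standardized to mean 0 and population
sd 1 over the 20 amino acids (the classical convention; standardizing per
dataset would make descriptors depend on the corpus). The eight default
scales are the standard octet used by protein-descriptor suites:
Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Bhaskaran–Ponnuswamy
flexibility, Grantham polarity, Charton–Charton polarizability, normalized
van der Waals volume, the Charton steric parameter and the Zimmerman
isoelectric point. The three estimators at lag d over per-residue property
values P with sequence mean P̄ are

- normalized Moreau–Broto: (1/(L−d)) Σ P_i P_{i+d}
- Moran: [(1/(L−d)) Σ (P_i−P̄)(P_{i+d}−P̄)] / [(1/L) Σ (P_i−P̄)²]
- Geary: [(1/(2(L−d))) Σ (P_i−P_{i+d})²] / [(1/(L−1)) Σ (P_i−P̄)²]

When every residue carries the same property value the Moran and Geary
denominators vanish; both return 0 by convention. Sequences shorter than
d_max+1 get zeros at infeasible lags (logged), keeping the matrix
rectangular.

CTD dialects differ in the distribution index rule, so it is fixed
explicitly: the k% occurrence of a class with n_c members is position
ceil(k·n_c/100) (at least the first), expressed as a chain-length fraction;
an absent class contributes five zeros. Transitions are unordered class
pairs over L−1 adjacent positions.

The disorder profile is a fold-index computed per residue over a centered
window (default 21, truncated at the termini): FI = 2.785·⟨H⟩ − |⟨q⟩| −
1.151, with ⟨H⟩ the windowed Kyte–Doolittle hydropathy rescaled to [0,1] and
⟨q⟩ the windowed mean of K/R (+1) and D/E (−1) charges. Residues with FI < 0
count as disordered.

Net charge in the physicochemical summary uses a fixed-pH model,
#(K,R) + 0.1·#(H) − #(D,E); isoelectric point and molecular weight come from
Biopython's `ProtParam`. The radius estimate uses the compact-globule
scaling law R = 2.2·L^0.38 (coefficient and exponent configurable) since no
structure is available. The twin-arginine motif [S/T]-R-R-x-F-L-K must start
within the first 35 residues. Signal-peptide and transmembrane calls are
consumed as optional annotations rather than predicted; a mean-hydropathy
heuristic over residues 1–25 would be a crude stand-in and is deliberately
not part of the default vector.

Non-canonical residues (B, Z, X, U, O) are rejected by default because the
property scales are defined only for the 20 canonical letters; a relaxed
policy strips them.

## Training-set construction

Positive expansion: for each family represented among the seed positives,
pool members of that family whose global-alignment identity to **every**
seed of the family is below 30% are ranked by increasing maximum identity to
those seeds (ties by accession) and the five most distant are recruited.
"Most distant" by maximum identity is a design choice (mean identity is the
obvious alternative); seed-vs-candidate rather than all-vs-all filtering is
likewise a choice, both configurable. Alignment uses match +1, mismatch 0,
gap open −10, gap extend −0.5, with identity = identical columns / total
columns.

Negative selection: any family containing a protein with saliva evidence is
contaminated, and a protein belonging to *any* contaminated family is
excluded (conservative direction for negatives; for positive expansion,
membership in any shared family qualifies). Remaining family members need at
least five plasma-proteome peptides; up to five per family are taken in
accession order.

## Feature selection

Stage 1 scores each feature by |Welch t| between classes and obtains a
permutation p-value by shuffling labels jointly across features,
p = (1 + #{|t*| ≥ |t|})/(1 + n_perm) (add-one, so p is never 0 and the
q-value machinery stays defined); 10,000 permutations by default. The
permutation loop is computed as batched matrix products of permutation
masks against the data and its square, which makes the 10,000-permutation
default run in seconds at 200×1,500. Storey q-values use a fixed λ = 0.5:
π̂₀ = min(1, #{p > λ}/((1−λ)m)), q(p_(i)) = min_{j≥i} π̂₀·m·p_(j)/j, capped
at 1. The fixed λ replaces the spline smoother for determinism; at m ≈ 1,500
the difference is negligible. Features with q < 0.005 survive.

Stage 2 ranks survivors by recursive feature elimination under a linear SVM
(C = 1), removing the ⌈10% of remaining⌉ lowest-w² features per round.
Before ranking, features with pairwise |Pearson r| > 0.98 are collapsed into
groups that are eliminated or retained as units — without this, duplicated
or near-duplicated descriptors split weight between themselves and all get
eliminated early. The final subset is the smallest nested set (by
elimination order) whose 10-fold CV recall and precision are each within
0.01 of the full survivor set, with fold assignments shared between the
baseline and every candidate subset so the comparison is paired.

A caveat worth knowing: because RFE ranks features by their *realized*
in-sample effects, same-data CV of the top-ranked subset is optimistic
(winner's curse), and the minimal subset can be smaller than the set of
truly informative features. On planted data with ten 2-sd features the
q-filter reliably keeps all ten, while the minimal subset is typically four
to six. The selection output therefore reports both the q-filter survivors
and the final subset.

## Classification and evaluation

The classifier is a soft-margin linear SVM, C = 1, uniform class weights
(no hyperparameters were dictated by the problem; all are configurable).
Cross-validation is stratified k-fold (default 10), reshuffled each repeat
from a seeded generator (default 100 repeats), with features standardized
using training-fold statistics only. Confusion counts are pooled over folds
within a repeat (micro-averaging) before computing recall and precision;
the grand mean over repeats is reported. The recall–precision curve sweeps
all distinct decision-score thresholds descending and the AUC is the
right-continuous step sum Σ(recall_k − recall_{k−1})·precision_k — never
linear interpolation, which is optimistic for PR curves. Degenerate
denominators (no positives evaluated, nothing predicted positive) yield 0
with a warning.

## Manifold ranking

All proteins (positives plus background) form a graph with Gaussian weights
W_ij = exp(−‖x_i−x_j‖²/2σ²) on standardized features, zero diagonal, σ
defaulting to the median pairwise distance. Above 2,000 nodes each node
keeps its 20 largest weights and the matrix is symmetrized by elementwise
maximum; below, the dense graph is exact. With S = D^(−1/2)WD^(−1/2) and y
the positive indicator, the iteration f ← αSf + (1−α)y (α = 0.99) converges
to (1−α)(I−αS)^(−1)y since ‖αS‖ ≤ α < 1; iteration stops when the maximum
absolute update is below 1e-9. Scores are non-negative and bounded by 1;
isolated nodes score 0. Positives stay in the graph (they drive the
propagation) but are excluded from the reported ordering; ties break by
accession for reproducibility. Ranking depth is assessed by the
hypergeometric probability of the observed overlap between a known set and
the top-n list.

## Differential expression and enrichment

Fold change is the ratio of summed case to summed control expression
(equivalently, ratio of means). The mean of per-pair ratios is available
behind a flag; ratio of sums is the default because a single near-zero
control value otherwise dominates. Genes pass with fc ≥ 1.5 or fc ≤ 1/1.5
(inclusive) and a two-sided paired-t p-value below 0.05 (the p cutoff is a
package default; only the fold threshold was dictated by the problem).
Zero-variance difference rows: all-zero differences give p = 1; a constant
nonzero shift gives the smallest positive float rather than 0.

Hypergeometric probabilities are computed in log-gamma space —
naive factorials overflow at N ≈ 20,000. Both the point mass
C(S,s)·C(N−S,n−s)/C(N,n) and the upper tail P(X ≥ s) are exposed: published
overlap surveys mix the two conventions, and the ranking-survey values this
package reproduces match the point mass at some depths and the upper tail at
others, so both routes are first-class.

## Synthetic data

The generator plants class signal **only** through residue-composition bias
(e.g., hydrophobic residues up-weighted 3× in positives), never by writing
values into the feature matrix, so descriptor computation, selection and
classification are exercised end to end. Lengths are uniform on 80–600;
families are assigned round-robin within each class and never shared across
classes, mirroring the saliva-clean family structure the negative-selection
rule assumes. Expression cohorts default to 43 paired samples and 1,000
genes with 100 planted effects at 2-fold (half up, half down as the
reciprocal) on a log-normal baseline (meanlog 7, sdlog 1) with log-normal
noise of sd 0.3 — the scale of a small paired tumour/normal microarray
study.

What passing tests on these fixtures show: the statistical machinery
recovers planted structure at realistic sizes and is calibrated under the
null. What they do not show: performance on real proteomes. Real protein
classes differ by far more than stationary composition (domain architecture,
signal peptides, post-translational context), real families carry shared
ancestry the i.i.d. generator lacks, and microarray data has platform and
batch effects the expression generator omits. Published headline accuracy on
curated training corpora is therefore not a quantity the synthetic fixtures
can, or attempt to, reproduce.

## Numerical and reproducibility choices

- Permutation p-values use the add-one rule; constant features get p = 1.
- q-values: fixed λ = 0.5, cap at 1, stable sort for ties; π̂₀ is floored at
  1/m so q stays strictly positive even when every p ≤ λ.
- SVM fits go through libsvm (scikit-learn `SVC`), deterministic for fixed
  inputs; RFE tie-breaks use stable argsort.
- PR-AUC collapses tied scores into single thresholds before stepping.
- Affinity σ = 0 (all-identical rows) is an error directing the user to an
  explicit σ; α→0 reduces ranking to the positive indicator.
- The pipeline fans a single global seed out to per-stage seeds by fixed
  offsets, so any stage can be reproduced in isolation; the manifest records
  input/output SHA-256 hashes, parameters and wall time per stage.
- Acceptance-script problem sizes (200 samples for CV checks, 10 replicate
  seeds for selection recovery, 100 synthetic proteins for the end-to-end
  run) are the package's chosen desk-scale study conditions; all scale with
  their spec objects.

## Known limitations

- The 1,302-element default vector implements all descriptor categories the
  method calls for, but element-level inventories vary between descriptor
  suites; the config exposes every block, scale list and lag ceiling so
  other dimensionalities are reachable.
- Negative training data is constructed by exclusion and inherits the
  incompleteness of saliva catalogs; the manifold ranking exists precisely
  to hedge this.
- The q < 0.005 filter needs n_perm ≫ m/(0.005·k) for k truly significant
  features to be detectable; with the default 10,000 permutations the
  smallest attainable q at m = 1,500 is ≈ 0.015/k, so very sparse signal at
  small m may require more permutations.
- Secondary-structure content and disorder are propensity summaries, not
  structure predictions.
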