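# Methods

This note records the models, conventions and design choices behind
`succsite`, in the spirit of a statistical-software methods appendix.

## Windowing

Candidate sites are lysines; each is represented by a 2r + 1 = 21-residue
fragment with the K at the center (r = 10). Positions overhanging a
terminus are padded with the ambiguity letter `X` and the pad counts are
kept on the window object. Padding (rather than dropping terminal sites)
keeps every labeled site usable; `X` was chosen because it is the
conventional "unknown residue" letter and every encoder defines its
treatment explicitly (below). Site lists that point at a non-K residue are
a hard error — silently skipping or relabeling would corrupt training
data. Coordinates are 1-based in all files.

## Encoders

**CKSAAP (2000).** For each gap k = 0..4 and each of the 400 ordered
standard-AA pairs, the count of occurrences at positions (i, i + k + 1)
divided by N_total = L − k − 1 (20, 19, 18, 17, 16 for a 21-mer). Pairs
touching a pad or ambiguity letter are not counted, but the denominator
stays N_total: padding can only lower pair fractions, never redistribute
mass to unrelated pairs. On a fully standard window each 400-block
therefore sums to exactly 1.

**Disorder (21).** The per-residue quantitative disorder scores are passed
through unchanged; padded positions contribute 0.0. The conventional 0.5
order/disorder boundary is exposed as a predicate (`is_disordered`) but
deliberately not applied to features — thresholding would discard signal
the classifier can use.

**PseAAC (40).** Type-1 pseudo amino acid composition with λ = 20 and
w = 0.05. The j-th sequence-order correlation factor averages, over residue
pairs (i, i + j), the mean of squared differences of three standardized
properties (hydrophobicity, hydrophilicity, side-chain mass; the classic
Chou-convention scales, shipped as packaged data in
`data/pseaac_properties.tsv` and swappable). Standardization is to zero
mean / unit population SD over the 20 amino acids. Composition frequencies
are fractions (Σf = 1), so all 20 + λ components share one denominator and
sum to 1 — a property the tests assert to 1e-9. Pairs involving pad or
ambiguity letters are dropped from the correlation average with the
divisor reduced; a window with no standard residues has undefined
composition and is an error. With L = 21 and λ = 20 the last correlation
factor averages a single term (i = 1); this is allowed and unit-tested.
Which property is called "H1" versus "H2" cannot affect the output (the
three properties enter symmetrically), so the field convention
(H1 = hydrophobicity) is used.

**PSSM (440).** The window-local 21×20 conservation-score matrix (sliced
from the protein-level PSI-BLAST profile; padded rows are zero, the neutral
element for both derived features) is flattened position-major — all 20
scores of position 1, then position 2, ... — giving 420 values, followed by
the 20 per-column means. The accompanying percentage matrix (PSFM) is
parsed and normalized to [0, 1] on read but not used in features. Columns
are remapped from the file header to a fixed canonical order
(A R N D C Q E G H I L K M F P S T W Y V) so features are stable across
PSI-BLAST versions.

Fusion order is CKSAAP, disorder, PseAAC, PSSM → 2501 dimensions, each
with a stable name `<block>:<local-index>:<description>`.

## Ranking and incremental feature selection

The gain ranker fits one LightGBM ensemble (100 iterations, fixed seed) on
all features and sorts by total split gain; the ANOVA ranker sorts by the
one-way F statistic (zero within-class variance with separated means maps
to +∞ and ranks first; all-constant features score 0). Both break score
ties by ascending original column index so rankings are bit-reproducible.
Other rankers can be plugged in as callables returning a ranked list.

IFS evaluates nested top-i subsets (step 1 by default) by stratified
k-fold CV and picks the smallest subset attaining the maximal fitness
(F-measure by default; ties → fewer features). Ranking and IFS are
separate stages, so a ranking from one method can feed any classifier. A
full 2501-step sweep at corpus scale is a cluster job; `max_size` bounds
the sweep for desk-scale work, and the bundled analyses use max_size = 50.

## Evaluation

Accuracy, recall, precision, MCC and F-measure from the confusion table.
Zero-denominator conventions: precision/recall/F-measure are 0 when their
denominator is empty; MCC is 0 when any marginal is empty. Folds are
stratified (keeps the class ratio stable per fold) and metrics are pooled
over out-of-fold predictions by default — pooling keeps MCC well-defined
with small folds — with per-fold bundles and macro-averages also returned.
`repeated_cv` repeats CV under distinct seeds and reports mean/std/max per
metric with the per-repeat values retained; at corpus scale the analogous
stability protocol wraps a full IFS sweep per repeat, which is reachable
by composing `run_ifs` over seeds.

## Hyperparameter tuning

Bayesian optimization minimizes the negated cross-validated F-measure.
Surrogate: Gaussian process with Matérn 5/2 ARD kernel plus white noise,
hyperparameters by marginal-likelihood maximization (the standard choice
for low-dimensional hyperparameter BO; the method itself prescribes only
"GP"). Acquisition: Expected Improvement (Probability of Improvement is
implemented and available), maximized by seeded random sampling of 2048
candidates per round — adequate for a 7-D space and trivially
reproducible. Encoding for the GP: numeric parameters scaled to [0, 1]
(reg_alpha log-scaled, since its range spans nine decades), categoricals
one-hot. Defaults n_init = 10, n_iter = 50 (the underlying study does not
state its budget). The search space mirrors the published table
(learning_rate (0.01, 1), max_depth (1, 50), max_bin (10, 100), reg_alpha
(1e-9, 1), boosting_type ∈ {gbdt, goss, rf, dart}, num_leaves (1→2, 50),
n_estimators (100, 600)); a num_leaves lower bound of 1 is meaningless for
leaf-wise trees and is clamped to 2 with a warning. The rf boosting mode
additionally requires bagging, which the CV objective enables
(subsample 0.8, every iteration) when that mode is sampled. Grid search
takes explicit per-parameter value lists (the published grid densities are
not stated, so none are hard-coded) and breaks ties toward the first point
in lexicographic grid order. Degenerate-σ acquisition limits:
a_EI = max(f_best − μ, 0); a_PI = 1 for strict improvement, else 0.

## Synthetic data

The generator emulates the *shape* of a curated succinylation corpus —
binary-labeled K-centered 21-mers with per-protein PSSM and disorder
files — with signal planted three ways: motif residues flanking the K in
positive windows (default: E at offsets ±1 with probability 0.9),
PSSM score shifts (+2, within the ±10 log-odds range typical of PSI-BLAST
output) in the motif residue's column at motif positions, and
class-contrasted disorder means (0.65 vs 0.35, SD 0.15, clipped to [0, 1]).
Background residues are uniform over the 20 standard AAs by default (a
Swiss-Prot-like frequency table is bundled as an option). One protein is
generated per site, long enough that labeled sites are interior (terminal
padding is exercised by dedicated tests instead). Setting the motif set
empty, the shift to 0 and equal disorder means yields a null dataset
(`SyntheticSpec.null`) on which any classifier should sit at chance — the
calibration the acceptance checks assert.

What passing on this generator does **not** show: real succinylation
motifs are weaker, position-distributed and confounded with homology;
real PSSMs and disorder tracks are correlated along the sequence and with
each other. The generator validates the machinery (formats, encoders,
selection, tuning), not biological performance; corpus-scale accuracy
claims require corpus-scale data.

## Problem sizes in the bundled analyses

The acceptance script and test suite run the pipeline at desk scale,
chosen as the package's own reference conditions: 1000-sample datasets
(500 per class) over 20 generator seeds for ranking recovery, IFS to 50
features at 10-fold CV, 10 × 400-sample null datasets for calibration, and
10-seed BO runs of 20 evaluations on a known quadratic. Oracle comparisons
use 1000 random confusion tables and 10⁶-draw Monte-Carlo Expected
Improvement.

## Known limitations

* PSI-BLAST and disorder predictions are consumed, not produced; profile
  quality (database release, iteration count) is the caller's concern.
* The exact property scales behind published PseAAC variants are often
  uncited; numeric values depend on the table chosen (dimensions and
  invariants do not), which is why the table is packaged data.
* No homology reduction is performed on input sequences.
* ReliefF / LinearSVR / XGBoost-importance rankers and PCA/t-SNE baselines
  are out of scope; the ranker interface accepts external implementations.
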