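# Methods

## Network model and cleaning

The interaction network is an undirected, unweighted simple graph over
opaque string identifiers. Edge-list input is cleaned on load: self-loops
are dropped (a node appearing only in a self-loop remains as an isolated
node), duplicate edges — including reversed orientation — collapse to
one, and extra columns (weights, evidence codes) are ignored with a
warning. Identifiers are compared verbatim after stripping surrounding
whitespace; there is no case folding, since gene-symbol case is
meaningful by convention. An edge list cannot express isolated nodes, so
an optional node-list file may add them; by default the node set is
edge-derived. The cleaned-network writer orders endpoints
lexicographically within a line and sorts lines, so equal graphs always
serialize to identical bytes and load/write round-trips are exact.

The positive gene set is intersected with the network's node set; genes
absent from the network are reported as unmapped, and an empty
intersection is an error (there would be nothing to characterize). How a
gene list was mapped to network identifiers is the user's concern — the
package deliberately does no remote symbol lookup, and pathway
membership is taken from a user-supplied two-column file (a gene may
belong to several pathways).

## Features

- **Degree**: neighbor count.
- **Core number**: computed by the standard O(|E|) peeling algorithm
  (networkx `core_number`); correctness is pinned in the tests against a
  literal recursive-removal oracle on randomized small graphs.
- **RNR**: positive direct neighbors / degree. The node's own label is
  excluded by construction (only neighbors count, and self-loops are
  gone). Isolated nodes get RNR = 0 rather than NaN so the classifier's
  feature matrix is total; the case is logged. Supplying positives not
  present in the network is an error rather than a silent intersection,
  to keep label bookkeeping explicit at the call site.

Degree and core number are label-free; RNR is the only label-dependent
feature, which drives the cross-validation design below.

## Characterization

Group summaries report per-group means of the three features for the
positive set, the background, and each pathway. Means are suppressed for
pathways with fewer than `min_group_size = 4` members in the network — a
mean over one to three proteins is noise; 4 is the smallest threshold
that keeps 8-member groups reportable while suppressing the degenerate
ones.

The two-sample Kolmogorov–Smirnov test (scipy `ks_2samp`) compares
feature distributions. The asymptotic p-value is the default because the
intended comparisons pit ~10²-sized positive sets against ~10⁴-sized
backgrounds; an exact method is available for small samples. Ties are
handled exactly by evaluating empirical CDFs at pooled sample points — no
jitter. One p-value per feature for positives-vs-negatives is the
primary output; per-pathway KS is exposed as an option. No
multiple-testing correction is applied across the three features.

Binned frequency distributions (percent per bin, summing to 100) take
user-supplied edges; the helper defaults are logarithmic for degree
(heavy-tailed in real PPI networks) and linear otherwise. Bins must
cover the data range — a value outside all bins is a caller error, not a
silent drop. Pathway overlap counts enumerate the inclusion–exclusion
partition of the named sets (the regions of a Venn diagram).

## Classifier

Features are scaled to [−1, 1] by an affine map fitted on training data
(`SymmetricMinMaxScaler`): min → −1, max → +1, constant feature → 0.
Test values outside the training range may land outside [−1, 1]; that is
the honest consequence of fitting on training data only and is left
uncorrected. The base model is sklearn's `SVC` (libsvm) with RBF kernel
at library defaults (C = 1, gamma = 1/(d·Var)), with polynomial-kernel
SVM and a decision tree as alternatives; no hyperparameter search, no
class weighting by default (both overridable via keyword or YAML
config).

Raw decision values become posterior probabilities through a calibrator
fitted on the training decision values. The default is a sigmoid (Platt)
fit maximizing the regularized likelihood with smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2), which stays finite on separable data
and is strictly monotone in the decision value. An equal-width binning
calibrator is provided as an alternative: empirical positive fraction
per bin with Laplace smoothing, monotonized by pool-adjacent-violators
and linearly interpolated between bin centers. Both are legitimate
readings of "convert decision values to posteriors"; the sigmoid is the
default because it is what libsvm itself implements internally.
Decision-tree models use the leaf positive fraction as the raw score
before calibration. Predicted labels use posterior ≥ 0.5.

## Evaluation

Stratified 5-fold cross-validation (each fold leaves out 20% of the
samples). Stratification is essential at realistic imbalance — ~1
positive per 100 negatives — where unstratified folds risk near-empty
positive test sets; the fold seed is an explicit, recorded parameter.
Per-fold and pooled confusion counts give precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R); degenerate denominators (no
predicted positives, no actual positives) yield 0 with an explicit flag,
never NaN. AUC is the normalized midrank Mann–Whitney U on posteriors
(ties count ½), pinned against a brute-force pairwise oracle in tests.

**RNR leakage policy.** Computing RNR once from all labels and then
cross-validating leaks test-fold labels into the feature. The default
`rnr_policy="per_fold"` recomputes every node's RNR (train and test)
against training-fold positives only, and fits scaling and calibration
on the training fold — an honest protocol whose fold models never see a
test label, verified by instrumentation in the tests.
`rnr_policy="global"` reproduces the common precomputed-feature protocol
and is recorded in the report so the two are never confused.

## Candidate prediction

The full-data model trains on positives vs all remaining nodes with the
global RNR — leakage is not a concern here because no held-out
evaluation is claimed for the candidate list. Non-positive nodes with
posterior > threshold are reported in descending order (identifier as
deterministic tie-break). The default threshold 0.5 is the natural
posterior cutoff and is configurable. The report carries seed, config
hash and leakage policy; re-running with the same seed and config yields
byte-identical output. Per-pathway classifiers reuse the CV machinery
with one pathway's members as positives and everything else negative;
reports with fewer than 30 positives are flagged `small_positive_set`,
since metrics there are dominated by sampling noise.

## Synthetic benchmark generator

The generator emulates the three contrasts the analysis assumes, at a
desk scale chosen once: a 2,000-node background at mean degree 6 (the
sparse regime of curated human PPI networks, and large enough that the
~1:40 class imbalance stresses stratification) with a 60-node planted
module. Planted nodes keep their background edges and additionally
receive (i) intra-set edges at probability 0.25 and (ii) 8 attachments
each to high-degree background hubs (top 5% by background degree). These
defaults reproduce the several-fold elevation of degree, coreness and
RNR observed for real curated gene sets (measured contrasts on seed 1:
28.8 vs 6.3 degree, 10.0 vs 3.8 coreness, 0.41 vs 0.04 RNR). Injection
is additive, which guarantees that strengthening any signal parameter
can only raise the planted module's statistics — a monotonicity the
tests exercise. Ten planted nodes are emitted unlabeled, modeling true
members hidden among the negatives; recovering them in the candidate
ranking is the end-to-end benchmark. The background is Erdős–Rényi by
default for analytic transparency; a preferential-attachment background
is available because real PPI degree distributions are heavy-tailed, and
the signal tests pass under both.

What the generator does *not* emulate: study bias (real degree
correlates with how intensively a protein is studied), the exact degree
sequence of any real interactome, pathway-specific topology, and
identifier-mapping noise. Passing the synthetic benchmarks therefore
demonstrates that the machinery is correct and that the features carry
the planted signal — not that any particular real gene set will separate
this cleanly.

## Numerical and design notes

- All randomness flows through explicit integer seeds (numpy
  `default_rng` and sklearn `random_state`); same seed, same output,
  including byte-identical candidate reports.
- KS p-values are clipped to ≤ 1; RNR is exact rational arithmetic in
  floating point (numerator an integer count, denominator the degree).
- Feature-table TSVs print RNR to 4 decimals; reading one back therefore
  quantizes RNR at 1e-4, which is the precision candidate reports use.
- Pooled CV metrics come from summed confusion counts; pooled AUC from
  the union of held-out posteriors across folds.
- Whether to stratify folds and where to put the candidate threshold
  were genuinely open choices: stratification was adopted for the
  imbalance argument above, and 0.5 as the most parsimonious posterior
  cutoff; both are parameters, not constants.
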