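# Methods

## Feature representation

The primary representation is the vector of overlapping k-mer occurrence
counts for all k in 1..6, in a fixed canonical order (ascending k,
lexicographic within k with A < C < G < T), giving Σₖ₌₁⁶ 4ᵏ = 5,460
features. Counts are raw occurrences rather than per-length frequencies:
normalization is delegated to the downstream standardization step, and a
`normalize_length` flag exists for users who want frequencies. Strands are
not collapsed; a `canonical` mode (credit each occurrence to the
lexicographic minimum of the k-mer and its reverse complement) is provided
but non-default. Windows containing a non-ACGT (IUPAC ambiguity) letter
contribute to no k-mer; this skip rule is the package's documented choice —
expanding ambiguity codes over their possibilities would make counts
non-integer and break the per-k row-sum identity Σ counts = L − k + 1 that
both the tests and the concatenation/reverse-complement properties rely on.
Counting uses a rolling 2-bit base encoding (O(L) per k); exact equality
with a naive position-by-position recount is the correctness contract and is
enforced in the test suite.

The alternative numeric-series representations for the binary task — DAX,
EIIP, Complementary, Enthalpy and Galois(4) coding schemes, and the three
dinucleotide physicochemical profiles (hydrogen bonding, stacking and
solvation energy per bp, computed from the first dinucleotide with a
one-base sliding window) — load their tables from versioned JSON config
files under `ltrstack/data/schemes/`. The numeric values are transcriptions
of the conventional literature tables (EIIP pseudopotentials; unified
nearest-neighbor duplex enthalpies; Ornstein-style stacking energies; mean
nucleobase hydration energies for the solvation table; integer digit
assignments for DAX/Galois(4); a signed injective map for Complementary
where Watson-Crick partners are negatives of each other). Tests pin the
files by checksum and assert structural properties (completeness over the
4 bases / 16 dinucleotides, finiteness, injectivity where the scheme must be
invertible) rather than specific numbers, so a revised transcription only
requires refreshing the checksum. Ambiguous bases map to each scheme's
neutral value (0). Equal-length input for classical estimators is obtained
by right-padding with the neutral value to the dataset maximum; truncation
is always an explicit error. The three physicochemical profiles are
concatenated by default, with a summary mode (mean + standard deviation per
profile, 6 features) as the compact alternative, since the original design
does not state which was used.

## Preprocessing

Features are standardized to zero mean and unit variance per feature
(min-max scaling is a config alternative), with parameters fitted on
training rows only. PCA retains the smallest number of components whose
cumulative explained variance reaches the target (default 0.96); a target
of exactly 1.0 retains the full rank min(n_samples − 1, n_features). The
decomposition tolerance (default 1e−4) is stored on the model and passed to
the solver when an iterative SVD solver (arpack/randomized) is selected; the
default full SVD is exact and has no tolerance knob. Fitting the reduction
on training rows only is a deliberate leakage-safe choice; for k-fold
cross-validation runs the folds share one decomposition fitted on the folded
data (the configuration a single CV estimate describes), while the
train/validation/test path never lets test rows influence the fit.

Splits default to stratified 80/10/10 with largest-remainder rounding, so
sizes are deterministic (n = 1,000 gives exactly 800/100/100) and per-class
proportions hold within one sample. Classes with fewer than 3 members are
placed entirely in training with a warning. Cross-validation uses stratified
k-fold (default k = 9) over the training domain; the held-out test set is
never folded.

## Classifiers and the stacking ensemble

The four retained base algorithms carry tuned defaults (KNN: 2 neighbors,
distance weights, Euclidean metric; linear SVC: C = 10⁻³, l2, squared
hinge, tol 0.1; logistic regression: C = 10⁻², tol 10, sag, l2, max_iter
1000; LDA: lsqr with shrinkage 10⁻⁴), and their exhaustive tuning grids are
available programmatically. Grid search maximizes mean cross-validated
weighted F1 with ties broken toward the first candidate in enumeration
order; a candidate that raises or fails to converge (degenerate corners such
as l1 + hinge, or metrics removed from the underlying library) is scored 0
and flagged rather than aborting the sweep. NB, MLP, DT and RF are exposed
with library defaults for single-hyper-parameter scans in the binary sweep.

The ensemble is a stacking classifier: base learners LDA + LinearSVC + KNN
(multiclass task) or KNN + LDA + LR (unified task), meta-classifier a
random forest with 500 trees and balanced class weights. The meta-learner is
trained on out-of-fold base predictions (internal seeded 5-fold) rather than
refit-on-full predictions, to avoid meta-overfitting. All seeds are
explicit, so fitting is deterministic on a given machine, and a fitted
pipeline serializes as a single `ModelBundle` archive whose predictions are
bitwise identical after a save/load round trip.

F1 aggregation is support-weighted by default (macro also reported) because
lineage supports span two orders of magnitude in real libraries; undefined
precision/recall from empty denominators are reported as 0 and flagged so
aggregates remain defined for rare classes. Multi-class ROC is one-vs-rest
with a macro average over classes having both positives and negatives.

## Feature selection

A LightGBM classifier with GOSS sampling and balanced class weights scores
each k-mer. The importance metric defaults to split count (whose magnitudes
make absolute thresholds like 60/40/30/20/10 meaningful), with total gain
available by flag. Selection keeps features scoring strictly above the
threshold, preserving vocabulary order, which makes subsets nested across a
descending threshold sweep; a rank-based `select_top_fraction` covers fixed
feature budgets such as "top 5%". The subset size at a given threshold is a
data-dependent output, never a constant. The desk-scale default is 500
estimators — the package's chosen operating point for interactive use — with
the 10,000-estimator configuration available via
`BoosterConfig.full_fidelity()`. Importance is computed on whatever matrix
the caller passes; scoring on training rows only is recommended, and scoring
on a full dataset (the classical protocol for this method) is simply a
matter of passing the full matrix.

## Synthetic data: what it emulates and what it does not

The generator emulates the structure of a curated plant LTR-RT library plus
a heterogeneous negative pool, so the entire pipeline can be exercised and
validated without external downloads. Per class, sequences are drawn from an
order-2 Markov chain (trinucleotide structure — rich enough that k-mers up
to 6 carry signal, cheap enough to generate in bulk); transition matrices
are convex mixtures (1 − s)·B + s·R_c of a shared background B and a
class-specific random matrix R_c, where s ∈ [0, 1] is the `separation`
knob. Class length regimes are log-normal with means interpolated the same
way between a shared background value and the class value, so that at s = 0
neither composition nor length carries any class information and classifier
performance is at chance by construction, while at s = 1 the defaults
reproduce the realistic regimes: Copia mean 5,957 bp, Gypsy 10,761 bp,
log-sigma 0.25 (a realistic library spread; the source statistics give
means, not dispersions). LTR classes carry an exact duplicated terminal
repeat (default 300 bp, the typical scale of plant LTRs) at both ends;
repeats are exact because the classifier under test is alignment-free and
gains nothing from simulated divergence, but an `ltr_divergence` mutation
knob exists. The negative class is a 0.5/0.3/0.2 mixture of codon-structured
CDS-like sequences (a distinct third-position chain, engaged proportionally
to s), short RNA-like sequences, and DNA-transposon-like sequences flanked
by 30-bp terminal inverted repeats, with means 1.2 kb / 0.8 kb / 3 kb. A
"table4" preset reproduces the published per-lineage imbalance scaled down
by 1/50 so generation stays under a minute.

What passing tests on this generator demonstrate: the pipeline recovers
planted compositional signal essentially perfectly at full separation,
degrades monotonically to chance as the signal is removed, and retains
performance under aggressive importance-based feature reduction. What they
do not demonstrate: performance on real repeat libraries, where lineage
signal is weaker and confounded (shared domains, nested insertions,
solo-LTRs, chimeric entries), where published full-scale results reach
weighted F1 in the mid-90s rather than ≈ 1.0. Synthetic recovery numbers
must not be read as benchmarks.

## Numerical choices and scales

Desk-scale defaults keep every experiment on one CPU in minutes: 100
sequences/class (1,400 total) for the recovery experiments, 9-fold CV, the
500-estimator booster, and k ≤ 6 features. The unified recovery experiment
runs in ≈ 2 minutes; the test suite in ≈ 8 minutes. Degenerate inputs are
handled explicitly: empty datasets, single-class labels, constant label
vectors, all-ambiguous sequences (zero count rows), classes smaller than
the stratification minimum, and empty selection results all raise or warn
as documented rather than propagating NaNs.

## Known limitations

* The synthetic negative pool is far cleaner than real annotation noise;
  chimeric and unclassified sequences are not modeled.
* Markov order 2 cannot express long-range structure (ORF order, PBS/PPT
  motifs); structure-based detectors' failure modes are out of scope.
* Encoded-series feature modes pad to the training maximum length; much
  longer prediction-time sequences are rejected rather than truncated.
* Grid-search fidelity: a handful of printed grid corners are invalid in
  the underlying library versions and are penalized (score 0) instead of
  evaluated.
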