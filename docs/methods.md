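# Methods

## Feature extraction

A genome is summarized by 101 single-strand composition statistics: the 4
mononucleotide and 16 dinucleotide absolute frequencies, the 16 relative
dinucleotide frequencies ρ_XY = f_XY/(f_X·f_Y), the 64 relative
trinucleotide frequencies γ_XYZ = f_XYZ·f_X·f_Y·f_Z/(f_XY·f_YZ·f_XNZ), and a
nucleic-acid indicator (+1 DNA / −1 RNA).  ρ is the classical dinucleotide
odds ratio; γ extends it to third order, dividing out every first- and
second-order effect including the gapped frequency f_XNZ (windows with any
middle base).  Both are ≈1 when the k-mer is exactly as abundant as expected
from lower-order composition, so deviations carry the host-specific
"genome signature".

Concrete counting conventions (several are genuinely open choices; these are
the ones implemented):

* **Normalization.** An absolute frequency is count / number of windows of
  that length: f_X over single positions, f_XY over length-2 windows, f_XYZ
  and f_XNZ over length-3 windows.  This makes ρ_XY the standard composition
  odds ratio; normalizing dinucleotide counts by L instead of L−1 would
  change every value by a factor (L−1)/L, irrelevant for classification but
  fixed here for reproducibility.
* **Ambiguity codes.** Any window containing an IUPAC ambiguity code is
  skipped and excluded from both numerator and denominator, so the 4-letter
  k-mer space is never contaminated.  f_XNZ consequently counts windows
  whose middle base is unambiguous.
* **Alphabet.** Input is case-insensitive; U is mapped to T before counting
  so DNA and RNA genomes share one alphabet.  The chemistry is carried by
  the indicator feature, which is a required user input, never inferred — a
  sequence alone cannot reveal it once U/T is normalized.
* **Zero denominators.** ρ and γ are defined as 0 whenever a denominator
  factor vanishes (low-complexity sequences), keeping vectors finite.
* **Order.**  mono (A,C,G,T), di absolute (AA..TT lexicographic), di
  relative, tri relative (AAA..TTT), indicator last.  The schema is frozen
  in `FEATURE_NAMES`.

Features are standardized to zero mean and unit variance with parameters
estimated on training data only; constant features map to exactly 0.

## Classifiers

Four probabilistic binary classifiers share one contract (positive class =
phage): logistic regression, kNN (odd k ∈ {1,3,5,7,9}, brute-force
neighbour search so distance ties resolve to the lowest training index),
QDA, and linear-kernel SVC.  The regularization grid for LR/SVC is the
consecutive powers of two 2⁻⁵..2⁵.

Two estimators needed package-level decisions:

* **SVC probabilities.**  A margin classifier has no native probabilities.
  `PlattSVC` fits the SVC, then a one-dimensional sigmoid (logistic
  regression on the training-set decision scores).  The mapping is monotone,
  so AUC is identical to that of the raw margins, and the whole fit is
  deterministic and invariant to sample order — an internally cross-validated
  calibrator would not be.
* **QDA covariance regularization.**  `RidgeQDA` models each class as a full
  Gaussian.  With fewer samples than features the sample covariance is
  singular, and a bare diagonal ridge makes held-out log-likelihoods
  dominated by noise in the near-null space (we observed held-out AUC
  degrading while training folds stayed perfect).  The default therefore
  estimates each class covariance with Ledoit–Wolf shrinkage — the standard
  well-conditioned estimator for n < p — plus a 1e-9 ridge as a
  degenerate-input guard.  `shrinkage="none"` recovers textbook QDA and is
  verified against scikit-learn's implementation on full-rank data.

Trained models are persisted as single-file bundles (estimator,
standardization parameters, feature subset, schema version); a reloaded
model reproduces probabilities bit-identically, and corrupted or
wrong-version files raise instead of returning garbage.

## Evaluation and the fitness criterion

MCC is computed at probability threshold 0.5 (0 when a denominator factor of
the closed form vanishes), AUC by the trapezoidal rule over the full ROC
curve, which equals the Mann–Whitney concordance statistic with ties counted
½ (asserted against an independent pairwise oracle in the tests).  Model
selection maximizes

    fitness = mean(MCC) + mean(AUC) − sd(MCC)/4 − sd(AUC)/4

over 5-fold cross-validation; the SDs are population SDs over the fold
values (the sample/population choice is not dictated by the criterion's
definition; population SD is fixed here and documented).  The criterion is
monotone increasing in both means and decreasing in both SDs, with global
maximum 2.  Fold construction defaults to stratified random folds from the
seed; the lineage-sorted folds from the partition module can be passed in
explicitly.

## Feature-subset search

All searches score subsets with the cross-validated fitness on a fold
assignment fixed once per search, and memoize every evaluation (the searches
revisit subsets by construction; the cache also guarantees the logged
fitness equals any re-evaluation).

* **Bottom-up search**: exhaustively evaluate all subsets of size 1..3; then
  repeatedly pick one of the top-100 subsets uniformly at random (the
  randomness is what prevents early convergence to a local fitness maximum),
  generate all one-feature-larger supersets, evaluate them and any unseen
  same-size subsets of each, and re-sort; stop when top-100 membership is
  stable for 1000 consecutive rounds.  At full scale the initial enumeration
  is 171,801 subsets; tests and examples run reduced universes (≤10
  features) with proportionally reduced top_k/patience.
* **Genetic algorithm**: individuals are 101-bit inclusion vectors;
  tournament selection (size 3), two-point crossover (p = 0.5), per-bit
  mutation (p = 1/n); a run stops at 200 generations or when the population
  is uniform; 5 independent repeats, best individual overall wins.  Operator
  settings are exposed as configuration, not hard-coded.
* **Embedded/filter selectors**: the L1 logistic-regression path over the C
  grid (subset = nonzero coefficients, C chosen by fitness); RFE driven by
  linear-SVC weight magnitudes, one feature eliminated per step, subset size
  chosen by fitness; ANOVA-F ranking with k chosen by fitness (constant
  columns get F = 0).  SCAD- and permutation-filter-based selectors are
  external-package methods and are deliberately not implemented; the CLI
  rejects them with a pointer to the supported methods.

The randomization test quantifies agreement between independently selected
subsets: each is replaced by a uniform random subset of the same size, all
are intersected, and 10⁶ repetitions yield the null distribution of the
intersection size.  The Monte-Carlo mean is checked against the closed form
U·Π(nᵢ/U), and the two-subset case against the exact hypergeometric tail.

## Lineage-aware partitioning

Class labels derive from the host lineage root (Bacteria/Archaea → phage;
Eukaryota → eukaryote-infecting, grouped by Spermatophyta / Vertebrata /
Arthropoda membership; "seed plants" are mapped to the taxon Spermatophyta).
Within each class, records are grouped into lineage blocks and sorted
alphabetically; every m-th block (m = round(1/test_fraction)) is held out as
the test set, so no lineage straddles the CV/test boundary — this is an
approximation to an unpublished partitioning procedure, chosen to satisfy
its stated goals (no redundancy between sets) without guessing unstated
detail.  Genome-type stratification is honored only when the metadata
provides a genome_type column.

Eukaryote-infecting viruses typically outnumber phages severalfold, so their
CV membership is thinned per lineage: the i-th virus of a lineage (1-based,
sorted by id) enters CV with probability P(vᵢ) = exp(−i^α).  The default
exponent α = 0.217; `optimize_alpha` re-fits it by bounded scalar
minimization of (E[count](α) − target)², where E[count] sums P(vᵢ) over all
lineages.  Since P(v₁) = e⁻¹ for every α, the attainable range is bounded
and infeasible targets return the boundary with a warning.  CV members of
each class are finally split, still lineage-sorted, into 5 contiguous folds
(sizes within 1).

## Fragment simulation

A fragment of length s is drawn by choosing a source genome with probability
proportional to its window count S−s+1 (sources shorter than s are
ineligible), a uniform start, and i.i.d. substitutions at rate r, each
replacing the base by one of the other three uniformly — the simplest
symmetric stand-in for both viral mutation and sequencing error.  Fragments
never wrap (linear genomes); sampling is with replacement; ambiguity codes
inside a window are left untouched and handled downstream by the extractor's
window-skipping.  Default sweep: s ∈ {100, 250, 500, 1000, 3000, 10000},
r ∈ {0, 0.02}.

## Synthetic corpora

The generator emulates the one property the method exploits — systematic
composition differences between host classes — with class-conditional
first-order Markov chains over {A,C,G,T}.  Transition matrices are built as
(1−λ)·1πᵀ + λ·I: stationary distribution π (parameterized by GC content)
with base-persistence λ, so the planted signal exists at the dinucleotide
level where the ρ features look, not just in base composition.  Defaults: 60
genomes per class of 1000–3000 bases; phage-like class GC 0.65, λ = 0.30,
95% DNA; eukaryote-like class GC 0.35, λ = 0.10, 50% DNA; 6 synthetic host
lineages per class so partitioning is exercisable.  These sizes keep a full
generate→extract→partition→train→evaluate cycle in seconds while leaving
both classes ≥5 CV members after thinning.

What the generator does **not** emulate: gene structure, codon usage, strand
asymmetries, CpG/TpA depletion mechanisms, database sampling bias, or any
realistic phylogenetic correlation between lineage label and composition
(lineages are assigned round-robin).  Passing end-to-end tests therefore
demonstrates that the pipeline recovers planted composition signal and is
correctly wired — not that the published real-data accuracies transfer.  The
null-control corpus (both classes drawn from one shared chain, equal DNA
fractions) verifies the other direction: without planted signal, CV AUC sits
at chance.

## Numerical and degenerate-input choices

* ρ/γ at zero denominators → 0; MCC at zero denominator factors → 0;
  standardization of constant features → 0.
* ROC thresholds: all distinct scores plus the sentinel, via the standard
  curve construction; AUC by trapezoid.
* kNN distance ties → lowest training index (brute-force search); even vote
  splits cannot occur with odd k.
* Subset canonical form: sorted unique index tuple; tie-breaks in search
  rankings are by canonical order, making every search deterministic given
  its seed.
* Exact integer arithmetic for subset counts (2ⁿ−1 up to n = 1000 without
  overflow).

## Known limitations

* Accuracies reported on real viral corpora require those corpora; nothing
  here downloads data, and the synthetic conditions are deliberately easy.
* Short fragments (< 500 nt) carry little composition signal; the simulator
  exists precisely to measure that decay.
* The sampling scheme balances class counts only in expectation; small
  corpora can deviate noticeably.
* SCAD and permutation-filter feature selectors are out of scope.
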