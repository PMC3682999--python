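# Methods

## Model and procedure

`ordsim` measures structural similarity between two sources of per-word
similarity values over a shared word set of size N:

- **decoding data**: row-normalized confusion matrices from repeated
  cross-validated single-trial classification, giving conditional
  probability estimates p_ij = P(predicted ω_j | true ω_i);
- **semantic models**: real-valued similarity matrices, either external
  (e.g. averages of expert-curated lexical-graph measures, supplied as
  labeled CSV) or computed in-package by latent semantic analysis.

For each focus word the row of values induces a strict partial order of
similarity differences (irreflexive, asymmetric, transitive; exact ties
incomparable), encoded as a binary connection matrix with
conn[i, j] = 1 iff value_j > value_i. Maximal chains of the order are
the paths from a minimal to a maximal node of its Hasse diagram; for an
order built from a real-valued row this is equivalent to sorting by
value and taking one representative per tie group in every combination,
so the chain count is the product of tie-group sizes. The orderings used
here are these maximal chains, not full linear extensions: a k-way tie
contributes k chains that each omit the other tied words, matching how
tied values shorten the printed orderings in the worked example.

The invariant structure of a brain-derived order and a model-derived
order is the set of all distinct maximal-length common subsequences over
all pairs of their maximal chains, deduplicated and ordered
lexicographically by word index. The element-wise AND of the two
connection matrices (itself always a strict partial order) is reported
alongside, and the invariant chains can be joined into one transitively
reduced DAG for display.

Significance is a fixed threshold on the tie-aware Spearman correlation
of the two rows (average ranks for ties, Pearson on ranks). The
threshold is the exact permutation null: over all N! untied rank
permutations, the smallest attainable ρ = 1 − 6Σd²/(N(N²−1)) whose
upper-tail probability is ≤ α/2 (two-sided convention; at N = 10,
α = 0.05 this is 0.6485 to four decimals, which is the convention under
which that published constant is reproduced — the one-sided value would
be 0.5636). The distribution is computed by a subset dynamic program
over Σ i·σ(i) (O(2^N·N) vector operations) rather than naive N!
enumeration; brute-force enumeration is kept as the test oracle for
N ≤ 8. For N > 10 the t approximation is used with a warning. A
constant row has no defined rank correlation and is counted as not
significant.

The headline statistic is the count of significant invariant partial
orders over repetitions: each (classification repetition, word) pair
contributes at most one, so 30 classifications of 10 words give a
maximum of 300. Significance is decided by the ρ criterion alone; no
minimum invariant-chain length is required (the chain content is
reported for inspection, not gated on).

## Classification pipeline

The decoder is a documented stand-in preserving the structure of the
original pipeline (linear discriminant, nested PCA, 5-fold CV), not a
reproduction of its internals:

- stratified k-fold assignment (default 5), deterministic in the seed;
- per-training-fold centering and PCA retaining the smallest component
  count reaching `pca_variance` (default 0.95; 1.0 keeps full rank);
- linear discriminant with pooled covariance and shrinkage
  (`shrinkage=None` selects Ledoit–Wolf automatically);
- **uniform class priors.** With unequal per-word trial counts,
  empirical priors push misclassifications toward frequent words, so the
  confusion structure would encode word base rates rather than waveform
  similarity. Uniform priors keep the off-diagonal structure — the
  quantity the ordinal analysis consumes — similarity-driven.

Epochs span `[onset + 10, onset + 10 + L)` samples on every channel
(160 ms onset offset at the 62.5 Hz effective rate), channels
concatenated; L is the floor of the mean over events of duration plus a
50-sample (~800 ms) extension. Epochs overrunning the recording are an
error, never padded, because padding silently changes feature
statistics. Ocular-artifact removal is out of scope; real recordings
must be pre-cleaned.

Bootstrap repetitions resample trials with replacement *within* each
class, preserving per-word counts so every word stays estimable in every
repetition. One caveat discovered and documented here: resampling
duplicates trials across CV training and test folds, so any classifier
that benefits from memorized duplicates reports inflated within-
repetition accuracy (on synthetic data, ~28% without resampling vs
~65% with). The repetition-to-repetition variability is still useful,
but accuracy under resampling should not be read as generalization
accuracy; the repeated-classification tests therefore use
`resample=False` (fresh fold seeds per repetition) where an unbiased
accuracy regime matters.

## Synthetic data generator

The generator emulates the statistical structure of the
geography-sentence decoding experiment: 15 channels at an effective
62.5 Hz, the four 10-word sets, per-word trial counts as used in the
experiment (640 trials for the first set), and 70-sample epochs
(~20-sample words plus the 50-sample extension). Per-word prototype
vectors are constructed so their Gram matrix approximates the
min-max-scaled target similarity matrix (symmetrized, eigenvalues
clipped at 0 if needed — tolerance 1e-8 — then factored and embedded in
channel × time feature space through a seeded orthonormal basis). Each
trial is `snr × prototype + unit Gaussian noise` per channel-sample,
planted in a continuous noise background at randomized trial order so
standard epoch extraction recovers exactly the planted windows. All
generators are pure functions of their seed (a single integer expanded
into independent substreams per stage).

What the generator does **not** model: EEG spectra (1/f background,
alpha), ocular or movement artifacts, volume conduction and channel
correlation, trial-to-trial latency jitter, and word-length differences.
Passing tests therefore show that the ordinal machinery recovers
similarity structure planted in this idealized regime; they do not show
robustness to real-EEG nuisance structure.

The default synthetic target similarity matrix is block-graded over the
geography words — within-group 0.7 (cities, countries, directions),
city–country 0.4, cross-group 0.2, unit diagonal, small seeded jitter to
break exact ties. It is a synthetic construction, not data from any
lexical database.

## End-to-end recovery conditions

The recovery property asks the full pipeline to tell the generating
model from a relabeled one: trials generated from the target matrix at
the experiment's scale (640 trials), classified at snr = 0.08 — chosen
once so single-trial accuracy falls in the observed 25–29% regime — with
three no-resample classifications per replicate, then scored by the
significant-invariant count against the true target and against a
decoy; the true target must win strictly in ≥ 95% of 20 seeded
replicates.

The decoy is a **group-scrambled relabeling**, not an arbitrary random
permutation. For a block-structured matrix, most random permutations map
the 3-word city and country blocks onto each other nearly intact, so the
"null" model retains most of the structure being tested (in piloting,
such decoys matched or beat the true target). The fixed derangement used
spreads every group's images across all three groups; by pigeonhole one
pair inside the 4-word direction group necessarily stays together, which
is the residual similarity a relabeling cannot remove.

## Numerical choices and degenerate inputs

- Ties are exact equality, optionally after rounding to `tie_decimals`
  (default: none). Printed-precision rounding reproduces published
  tables where 0.00 and 0.000 are tied.
- Matrix CSVs are written with repr precision and read back with
  round-trip float parsing, so write→read is bit-exact.
- When two labeled matrices are combined, label sets must match exactly;
  the second is permuted to the first's order. Silent intersection is an
  error because it corrupts N-dependent statistics.
- Row normalization of a confusion matrix with an empty row (a word with
  no test samples) is an error naming the word.
- Complete-linkage similarity trees symmetrize the input, use
  d = s_max − s by default (s_max over off-diagonal entries) with
  d = 1 − s available for matrices already in [0, 1]; merge ties break
  deterministically and heights are non-decreasing.
- LSA uses log-entropy weighting by default (tf available), truncates
  the SVD at min(max_factors, numerical rank), and computes cosines of
  term rows scaled by singular values; a word absent from the corpus is
  an error naming the word.
- Whether stacked similarity measures are rescaled before averaging is
  exposed (`normalization="minmax"`), not asserted, since either
  convention is defensible.

## Problem sizes in the test suite

Classification-heavy tests run on a reduced generator (5 words,
20 trials each, 6 channels) so the full suite stays within a couple of
minutes; the recovery property and the 640-trial condition checks run at
the experiment's full scale (~2 minutes). Exact-null oracles enumerate
up to 8! permutations; the subset DP covers N = 10 in milliseconds.

## Known limitations

- The decoder is a stand-in; published per-participant decoding rates
  depend on undeposited recordings and a proprietary pipeline, and are
  not reproduced.
- The worked-example Spearman value printed here (0.9240 for the London
  rows) is computed with average-rank tie handling; other tie
  conventions give different descriptive values.
- Maximal-chain and common-subsequence enumeration is exponential in the
  number and size of tie groups; fine for the ~10-word sets the method
  targets, not for hundreds of heavily tied classes.
- Semiorders/interval orders (threshold-based tie handling) and general
  maximum-common-subgraph isomorphism are out of scope.
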