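# Methods

This note documents the models and procedures `nomtrait` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical edge cases the implementation pins down.

## Data model and screening

A `TraitMatrix` is an n × m grid of category labels over explicit, ordered
per-trait category sets, each trait tagged with a functional role (diet,
habitat, morphology, life history). Validation is strict: duplicate ids,
labels outside a closed category set, or traits absent from the codebook are
errors, not warnings — silent category drift is the classic failure mode of
hand-curated trait tables.

Traits with too much missingness are dropped before imputation; the default
cutoff retains traits with missing fraction strictly below 0.25, reflecting
the common finding that imputation accuracy in small categorical datasets
degrades sharply above ~20–25%. The packaged 21-trait catalogue
(`nomtrait/data/trait_catalogue.csv`) transcribes a published coastal-fish
trait table — category sets, function tags and per-trait missing percents
(13 traits fully observed, worst trait 23.3%). The working matrix that
table describes is reported as 22 traits while the table itself lists 21
rows; the package ships the 21 published rows and pads the synthetic
default to m = 22 with one extra 4-category trait, documenting rather than
resolving the discrepancy. `catalogue_fixture_matrix()` builds a **synthetic**
116-row matrix reproducing exactly the catalogue's missingness pattern (the
underlying real matrix is not public); only its missingness and category
sets are meaningful, not its values.

Continuous traits (length, depth) enter as ordered bins. `suggest_bins`
places breakpoints at equal widths on the natural-log scale — appropriate
for roughly log-normal size variables — and the catalogue's published
breakpoints (20.1, 54.6, 148.4, 403.4) are e³…e⁶ to one decimal, shipped
verbatim as `CATALOGUE_BINS`. Intervals are right-closed with the first
bin closed below and the last unbounded, so every finite value maps to
exactly one label; boundary values are assigned deterministically to the
lower bin.

## Synthetic generator

`generate(SyntheticSpec)` draws a planted-partition nominal matrix:
species are assigned to `n_groups` balanced groups; each group has a
preferred category per trait, assigned **cyclically** across traits
(group j prefers category (j + c) mod K_c in trait c) so no single trait
separates all groups — mimicking the redundancy of real trait suites. A
cell equals its group's preferred category with probability θ, any other
category with the remaining mass spread uniformly. θ = 1/K_c is exactly
uniform (zero signal); θ = 1 makes group rows identical. The default spec
mirrors the shape of the motivating study: n = 116, m = 22, category
counts from the catalogue, 3 groups, θ = 0.9.

What it does **not** emulate: phylogenetic correlation between species,
ordered (ordinal) trait structure, unequal group sizes, trait-specific
signal strengths, and missingness that depends on the trait value (only
MCAR is generated). Passing tests on this generator therefore demonstrate
correctness of the machinery and behavior under idealized group structure,
not performance guarantees on real assemblages.

`ampute_mcar` deletes exactly round(p·n·m) cells uniformly without
replacement and returns the true values as a mask. Deleting an entire
column is an error (imputers need one observed value per trait); a
proportion that rounds to zero deletions is an error unless explicitly
allowed as a no-op.

## Imputation

`impute_mode` replaces each missing cell with the trait's most frequent
observed category, ties broken by codebook order (deterministic). Its
expected accuracy under MCAR is the modal relative frequency — the test
suite checks this analytic baseline.

`impute_polytomous` is a chained-equations scheme: initialize by mode;
then for each trait in turn fit a multinomial logistic regression of that
trait on one-hot encodings of all other traits (observed rows only) and
redraw the trait's missing cells from the fitted category probabilities;
sweep all traits for `iterations` rounds.

- **Iterations default 5.** The literature's usual chained-equations
  default; accuracy on the synthetic fixtures plateaus well before that.
- **Draws, not argmax.** Sampling from fitted probabilities is proper
  imputation and preserves between-cell variability; a deterministic
  argmax mode is available via `draw=False`.
- **Ridge penalty 1e-3** on the one-hot coefficients (L2): with ~100
  species and fully dummy-coded predictors, separation is common and an
  unpenalized fit diverges. Non-convergence after regularization falls
  back to the mode initialization for that trait, with a logged warning.
- External imputers (random forest, multiple correspondence analysis)
  attach through `register_imputer(name, fn)`; they are deliberately not
  reimplemented.

`benchmark_imputers` runs the amputation experiment: proportions default
0.05…0.45 in steps of 0.05, 100 replicates, every method scored on the
same amputed matrix per replicate. Accuracy is the **proportion of masked
cells restored correctly**; the 95% interval is mean ± 1.96·SE across
replicates. One subtlety the tests make explicit: on a *fixed* finite
matrix drawn from an independence model, a regression imputer genuinely
exploits realized in-sample associations (masked cells are sample values),
so "no better than mode under independence" only holds once n is large
enough that those associations vanish — the property is checked at
n = 500, where the measured artifact is below noise (it is ≈ +0.02
accuracy at n = 150 and ≈ 0 by n = 800).

## Dissimilarity measures

Five per-attribute similarity functions (SM, Eskin, IOF, Goodall, Lin) as
tabulated in the README; object dissimilarity is 1 − S by default with the
reciprocal transform 1/S − 1 behind a flag. Natural logarithms throughout.
Frequencies are always recomputed from the matrix actually passed — a
bootstrap resample is treated as a self-contained dataset, which matters
for every frequency-weighted measure.

Pinned edge behavior:

- **Goodall** scores a match as 1 − p̂₂ (pair estimate), so two *identical*
  rows have dissimilarity mean_c p̂₂(x_c) > 0 whenever any shared category
  occurs more than once. This follows from the definition and is asserted
  in the tests; the diagonal is 0 by construction. A match on a globally
  unique category (f = 1) scores exactly 1.
- **IOF** gives mismatches between two singleton categories (f = 1 both
  sides) similarity 1/(1 + 0·0) = 1: such a mismatch costs nothing. This
  is the published form's behavior, kept and documented.
- **Lin** pairs where every trait is single-valued have a zero normalizer;
  their dissimilarity is defined as 0 with a runtime warning.
- The Goodall variant implemented is the "match weighted by one minus the
  pair estimate, mismatch zero" form — the variant most measure surveys
  list under Goodall's name; the transform and variant are both isolated
  behind the module surface should a different convention be needed.

## Clustering

Agglomeration is the direct O(n³) scheme with Lance–Williams updates
(single = min, complete = max, average = size-weighted mean, algebraically
identical to the mean over all cross-pairs). At n ≈ 100–150 this is
milliseconds; nothing faster is warranted. Ties among equally close pairs
merge the pair with the lexicographically lowest (smaller, larger) cluster
ids, making dendrograms bit-reproducible across platforms. The test suite
checks the merge table against a naive cross-pair re-enumeration oracle on
random instances and against scipy's independent implementation on
tie-free inputs. Heights are non-decreasing for all three linkages (no
inversions are possible for min/max/mean updates); `cut_tree(k)` undoes
the last k − 1 merges, and cuts from one tree are nested.

PAM is classic BUILD (greedy seeding from the distance-sum minimizer) plus
SWAP (apply the best improving medoid/non-medoid exchange until none
remains). Both phases are deterministic, so PAM takes no seed. SWAP is a
local search: the returned medoid set is exactly swap-optimal (tested
exhaustively), reaches the global optimum on the k = n − 1 closest-pair
case and on the large majority of tiny random instances, but global
optimality is not guaranteed — nor claimed.

## Validity indices and choosing k

WCE is the size-weighted mean per-cluster, per-trait Shannon entropy
(0·ln 0 ≡ 0), 0 iff every cluster is single-valued on every trait; it
never increases under refinement (entropy concavity — property-tested).
PSFE(k) = (n−k)[nWCE(1) − nWCE(k)] / ((k−1)·nWCE(k)); the factor n in
nWCE cancels, so the statistic is insensitive to whether "total
variability" is read as WCE or n·WCE. Gini twins replace the entropy term
with impurity 1 − Σp²; the Gini pseudo-F is built with the identical
normalization (the structure-matching reading, since no alternative
normalization is pinned anywhere authoritative).

Degenerate cases: WCE(k) = 0 with WCE(1) > 0 means perfect clusters —
PSFE is reported as +inf and outranks every finite value in `select_k`
(a perfect clustering should win, not error); WCE(1) = 0 (no variability
at all) makes the ratio meaningless — NaN, excluded from the argmax, and
all-NaN is an error. Ties in `select_k` go to the smallest k (default
grid 2…10). ΔWCE(k) = WCE(k−1) − WCE(k) requires consecutive k from
nested cuts and is non-negative there.

The adjusted Rand index is the Hubert–Arabie chance-corrected form
(delegated to scikit-learn behind the module surface; the test oracle is
an explicit pair-counting implementation). Partitions are aligned by
object id before comparison.

## Bootstrap stability

Reference partition: PAM at k on the full matrix. Each of B replicates
(default 100) draws n species with replacement, recomputes frequencies and
the dissimilarity matrix on the resample, re-runs PAM, and records for
each reference cluster the **maximum** Jaccard coefficient against the
replicate's clusters — no one-to-one assignment, following the standard
cluster-wise stability scheme. Comparisons use unique object identities:
a species drawn twice counts once in both set arguments. Resamples with
fewer than k distinct species are redrawn (counted in the report).
Jaccard of two empty sets is defined as 1 (a reference cluster absent
from the resample gives no evidence of instability).

On the default fixture, mean Jaccard at the planted k is 1.0 at θ = 1 and
decreases with θ, with monotonicity across θ ∈ {0.5, 0.7, 0.9, 1.0}
checked at the 3-seed median with B = 50.

## Pipeline, embedding, reproducibility

`run_pipeline` executes screen → impute → (measures × linkages) →
validity grid → pairwise adjusted-Rand tables at chosen k → bootstrap
stability → 2-D embedding, writing plain CSV/JSON/Newick artifacts and a
manifest with per-file SHA-256 hashes. One master seed derives a fixed
sub-seed per stochastic stage, so a rerun with the same config is
byte-identical (tested). The 2-D embedding is t-SNE on the precomputed
dissimilarity matrix (scikit-learn), perplexity clamped below n, seeded;
it is a visualization aid only and no inference is drawn from it. An
all-zero matrix returns origin-stacked coordinates with a warning rather
than crashing.

## Problem sizes used by the test and acceptance runs

Unit and property tests run on matrices of n ≤ 20 with brute-force
oracles at n ≤ 10. Study-scale checks use the default fixture
(116 × 22, 3 groups): recovery and model selection over 100 simulated
matrices; the imputation benchmark at 100 replicates per proportion;
stability at B = 100 (full) and B = 50 × 3 seeds (θ sweep); the
independence property for the polytomous imputer at n = 500. These sizes
make the whole suite run in a few minutes while keeping every replicate
count at its conventional value (100) where a convention exists.

## Known limitations

- Mixed continuous–nominal distance measures are out of scope; continuous
  traits must be discretized first, which discards within-bin information.
- Only MCAR missingness is generated and benchmarked; imputation accuracy
  under informative missingness is not characterized.
- PAM provides locally optimal medoids; stability results inherit that.
- The Goodall implementation is one variant of a family; surveys list
  several, and no supplementary source pinning the exact variant was
  available — the choice is documented above and isolated behind the API.
- Validity indices compare partitions of the *same* data; they do not test
  whether any cluster structure exists at all (a structureless matrix
  still yields an argmax k).
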