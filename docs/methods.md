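# Methods

## Signed weighted topological overlap

For each dataset, every GRF is Spearman-rank correlated (average ranks on
ties) against every expressed gene; two-sided p-values come from the
t-approximation with n − 2 degrees of freedom on the rank correlation
(an exact permutation p, conditional on the observed rank vectors, is
available for n ≤ 9 samples). Entries with p ≥ α (default 0.05) are set
to zero, the GRF–GRF diagonal is forced to zero, and the GRF–GRF block is
asserted symmetric rather than symmetrized — asymmetry indicates an input
error, not numerical fuzz. Constant genes get ρ = 0, p = 1 (logged), so
downstream matrices stay complete.

The overlap statistic for a GRF pair (i, j) is

ω_ij = (c_ij + a_ij) / (min(K_i, K_j) + 1 − |a_ij|),

with c_ij = Σ_{u∉{i,j}} a_iu·a_ju and K_i = Σ_{u≠i} |a_iu|. Two
conventions matter and are deliberate:

* **K uses absolute values.** A signed sum can make the denominator
  smaller than the numerator and push |ω| beyond 1, contradicting the
  signed-range semantics of the statistic; the absolute-value form
  guarantees ω ∈ [−1, 1] (K_i ≥ |a_ij| also makes the denominator ≥ 1, so
  no division guard is needed) and reduces to the classical topological
  overlap when A is non-negative.
* **u excludes both endpoints in c_ij, while K_i excludes only i.** This
  is what makes a "perfect module" — both GRFs correlated +1 with the
  same k neighbors and with each other — come out exactly ω = 1.

Because a_ii = 0, the excluded terms of c_ij vanish from the matrix
product, so C = A·Aᵀ computes the excluded sum directly; a deliberately
loop-based reference implementation (`wto_brute_force`) is kept as an
independent oracle and cross-checked in the tests to 1e−10.

The overlap universe u defaults to *all* expressed genes ("all_genes"),
since GRFs are correlated against the full transcriptome; a "grf_only"
mode restricts u to the GRF set for users who want the network to be
self-contained. Both are exact; they answer slightly different questions
about shared neighborhoods.

## Permutation-null calibration

Reliability of a network is assessed by reshuffling expression values
across genes *independently within each sample* — each individual keeps
exactly their value multiset, but gene identity is destroyed — and
recomputing the entire correlation → threshold → wTO pipeline per
permutation (default 100). Link counts at a cutoff grid (0.1–0.6, step
0.1) are compared between real and permuted networks:

* empirical p(cutoff) = (1 + #{perm count ≥ real count}) / (1 + n_perm);
  the add-one pseudocount keeps p > 0 with finite permutations, and ties
  count against significance.
* false-positive rate = mean permuted count / real count, reported as NaN
  when the real network has no links at that cutoff.
* the smallest cutoff with empirical p < 0.01 is reported as the
  recommended per-dataset cutoff; the mean of these across datasets can
  serve as the consensus threshold (`mean_calibrated_cutoff`).

Randomness uses one master seed with per-permutation substreams
(`default_rng([seed, i])`), so results are reproducible and independent
of evaluation order.

## Consensus integration

Per-dataset networks are aligned over the union of GRF pairs (canonical
lexicographic ordering; a pair is missing in a dataset iff a member GRF is
absent there — an ω of exactly 0 is a defined value, not missingness).
For every pair observed in at least `min_present` datasets (default: all),
the |ω| sample is tested against the location threshold (default 0.3) with
a one-sample Wilcoxon signed-rank test, alternative "greater". Links with
p < α get the **median of the signed ω values** as weight, the count of
defined datasets, and a `sign_consistent` flag (all defined ω strictly one
sign). The test runs on |ω| while the weight keeps signs; mixed-sign pairs
are therefore possible and flagged rather than dropped, and their median
is near zero.

Test mechanics: zero differences are dropped before ranking; if all are
zero, p = 1. Differences are rounded to 12 decimals first so that equal
spacings (0.4 − 0.3 vs 0.3 − 0.2) do not acquire artificial rank order
from floating-point representation. For n ≤ 25 the null is computed
*exactly* by sign-flip enumeration conditional on the observed |d| —
implemented as an O(n³) dynamic program over doubled (integer) average
ranks, so tied magnitudes are handled exactly; beyond n = 25 a normal
approximation with tie-corrected variance (scipy) is used. With all ten
differences positive the exact one-sided p is 2⁻¹⁰ ≈ 9.77 × 10⁻⁴, the
floor of the test at n = 10; below n = 5 the exact test cannot reach
0.05, which is why `min_present` values under 5 silently admit no links.

A pair strong in one dataset and near zero in the rest (e.g. ω = 0.9
once, ≈ 0 nine times) is rejected by construction — the point of testing
the whole distribution instead of averaging.

## Expression filtering

RPKM-like matrices keep genes with value strictly > 0.5 in at least
⌈0.9·n⌉ samples (ceiling chosen for determinism on small n; the value
comparison is strict, the count comparison inclusive). Probe-level
microarray matrices keep probes with detection p < 0.05 in ≥ 1 sample and
collapse multi-probe genes to the per-sample arithmetic mean. Filters
never reorder samples or alter retained values, and missing entries are a
hard error by default (a drop-row fallback is explicit); values are never
imputed. Upstream summarization (RMA/MAS5, read mapping, RPKM
quantification) is out of scope — matrices arrive already summarized.

## Downstream analytics

* Degree is sign-blind; hubs are nodes with degree strictly above a floor
  (default 25, meaningful only at real-catalog scale; examples use lower
  floors).
* Group connectivity uses the unpaired one-sided rank-sum test
  (scipy `mannwhitneyu`; exact for small untied samples).
* Gene-set overlap: upper-tail hypergeometric p (identical to one-sided
  Fisher on the 2×2 table, cross-checked in tests), odds ratio with
  Haldane 0.5 correction on zero cells, BH adjustment across batches
  (statsmodels behind the package's own surface), and two-way permutation
  validation — the external permutation resamples the annotation set from
  the background, the internal one resamples the query set from a
  caller-supplied expressed pool; both use the add-one pseudocount. All
  three sets are explicit inputs; no background is hard-coded.
* Outliers use hinge quartiles (R `fivenum`/`boxplot.stats` convention,
  verified against R) with Tukey fences at 1.5·IQR.
* Dataset comparison: Euclidean distances over pairwise-complete shared
  pairs, embedded by classical (Torgerson) metric scaling — double
  centering plus the top-2 spectral decomposition, negative eigenvalues
  truncated at zero; coordinates are defined up to rotation/reflection.
  sklearn's MDS is SMACOF rather than classical, so this is implemented
  directly (a few lines) and tested on exactly 2-embeddable metrics.

## Synthetic study conditions

The generator is a one-latent-factor-per-module linear model: module m
has activity z_m ~ N(0, 1) per sample; member gene g expresses
β·sign_g·z_m + ε with ε ~ N(0, noise_sd); non-module genes are pure
noise. Defaults — frozen as the package's study conditions — are 10
datasets × 20 samples, 20 GRFs with two planted modules of 5 (module 2
carries one negative loading so the sign rule is exercised), β = 0.85,
noise_sd = 0.4, 200 target genes assigned round-robin to modules with
random signs, and a +10 baseline so matrices are valid non-negative
RPKM-like input for the filters. Module assignments are fixed across
datasets; samples are independent draws, making the datasets biological
replicates with known ground truth: every within-module GRF pair is an
expected link with sign equal to the product of the member loadings.

The population Spearman correlation between two same-module members is
monotone in β²/(β² + noise_sd²) ≈ 0.82 at the defaults, high enough that
single-dataset networks still contain spurious links (low-connectivity
noise GRFs with a few chance correlations produce inflated ω — visible in
the examples), which is precisely the failure mode the consensus step
removes. What the generator does **not** model: count noise, platform
differences, batch effects, age trajectories, or cell-type mixtures — so
passing tests demonstrate the statistical machinery works as specified,
not that any particular biological dataset will behave this way.

## Problem sizes and numerics

Tests and the acceptance script run at 200–220 genes, 10–20 GRFs, 10–20
samples, 100 permutations, and 10,000 random matrices for the bound check
— sizes chosen so the full suite completes in well under a minute while
every code path (including the permutation null recomputing ~2,000 full
networks) is exercised at meaningful signal-to-noise. The wTO oracle
comparison uses 1e−10; edge-list round-trips use %.17g floats and are
exact to 1e−12. Matrices are validated complete and finite at every
boundary; empty filter results are warnings, not errors.

## Known limitations

* The consensus test's power floor means small dataset collections
  (D < 5 present values) can never produce links at α = 0.05.
* `degrees` of a consensus network only knows nodes that carry links;
  zero-degree GRFs must be reindexed in from the catalog (as example 04
  does) before group comparisons.
* The exact Spearman p option enumerates n! pairings and is gated to
  n ≤ 9; beyond tiny pilot data the t-approximation is the intended path.
* Identifier namespaces are opaque strings; no gene-symbol translation is
  attempted.
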