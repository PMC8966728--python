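# Methods

This note documents the models, conventions and numerical choices behind
`formsem`, in the order the pipeline runs.

## Input model and normalization

A lexicon row is one sign entry: a gloss, an optional variant index, and
categorical labels over a fixed twelve-slot schema (handshape and location
for dominant/non-dominant hand at sign begin/end; local movement, path
movement, axis, non-dominant-hand behavior).  Empty cells are *missing
slots*, not a label level: a one-handed sign simply contributes an all-zero
block in the non-dominant columns.  The alternative — an explicit "absent"
feature — would make any two one-handed signs more similar merely for both
lacking a second hand, over and above what shared absence already does to
the cosine; the zero-block convention is the more conservative reading.

Glosses are normalized to lowercase, surrounding whitespace stripped,
internal whitespace replaced by a single hyphen.  The rule exists to maximize
exact matches against embedding vocabularies (which are lowercase single
tokens); no lemmatization or subword fallback is attempted, so multi-word
glosses match only if the embedding vocabulary happens to contain the
hyphenated form.  Duplicate glosses are resolved by keeping the first listed
entry (row order is authoritative; a variant column, when present, is
carried through but not used for selection).

## Phonological space

Per parameter scope (handshape = 4 slots, location = 4, movement = 4,
entire = all 12), signs are one-hot encoded over the sorted union of
observed (slot, label) pairs, giving a binary matrix **X** with exactly one
1 per present slot.  **X** is reduced by truncated SVD; a sign's coordinates
are the rows of `U_k Σ_k`.

* **Rank.**  Default `k = min(50, min(n_signs, n_features))`.  No principled
  rank is known for this kind of data, so the default favors a dense,
  generalization-friendly representation while `k = "full"` provides the
  exact limit in which reduced-space cosines equal raw one-hot cosines
  (asserted to 1e-9 in the tests).  Results that should not depend on the
  encoding (oracle comparisons, the synthetic benchmark) are computed in the
  full-rank limit.
* **Determinism.**  SVD sign indeterminacy is fixed by flipping each
  singular vector so the largest-magnitude component of the right singular
  vector is positive.  Cosines are sign-invariant per component pair, so
  this affects nothing numerically; it makes outputs byte-reproducible.
* **"Entire" scope.**  The twelve slot blocks are concatenated before the
  SVD (not an average of per-parameter similarities), and all slots weigh
  equally.  This is the simplest composition; a per-parameter weighting hook
  would be the natural extension if one parameter's larger inventory is
  found to dominate.
* **Degenerate rows.**  A sign with no annotation in a scope has a zero row;
  every similarity involving it is *undefined* (NaN) and the pair is
  excluded listwise from that scope's correlation, with a logged count —
  never imputed as 0.

## Semantic space

Embeddings are read from GloVe plain-text files (token + d floats per line;
gzip transparent).  Malformed lines are skipped and counted; duplicate
tokens keep their first occurrence.  Signs whose normalized gloss has no
vector are dropped at alignment, and the per-scope phonological spaces are
rebuilt over the retained entries so semantic rows, phonological rows and
entries stay index-aligned.  No SVD is applied to the semantic vectors; they
are used at their native dimension.

## Pairwise analysis

All `n(n−1)/2` unordered pairs, lexicographic order.  The association per
scope is the sample Pearson correlation between semantic and phonological
cosine similarity, with a two-sided p-value from the exact t transform
(`df = n_pairs − 2`), significance at α = 0.001 by default, no family-wise
correction (a Bonferroni pass over the sweep grid is easy to apply
downstream but is off by default so individual cells remain comparable).

The correlation is accumulated over row blocks of the cosine matrices
(default 512 rows), combining centered sufficient statistics around a pilot
mean taken from the first block; this keeps memory linear in n and the
final cancellation harmless at millions of pairs.  The streaming result is
asserted equal (1e-10) to the materialized-pair-table computation in the
tests.  Note the t-test treats pairs as independent although pairs sharing
a sign are not; the synthetic null calibration below measures the practical
consequence (rejection rate at α = 0.001 stays at or below 1%).

## Clustering analysis

* **Linkage.**  Ward's minimum-variance criterion on Euclidean distance over
  the semantic vectors, computed by scipy's nearest-neighbor-chain
  implementation (deterministic; merge heights are monotone).  Equal-cost
  merge ties are resolved by scipy's internal order; on the continuous
  random and Gaussian inputs used throughout, ties occur with probability
  zero.  Correctness is pinned by an independent O(n³) Lance–Williams
  implementation in the test suite (100 random instances, n ≤ 40, 1e-9).
* **Cuts.**  Pruning heights are percentages of the maximum merge height.
  The default grid is 1..100 inclusive: 0% is degenerate (every sign a
  singleton, no within-cluster pairs) and is excluded by default but
  accepted by the API.  Cluster ids are relabeled by smallest member index
  so labelings are stable across runs.
* **Silhouette.**  Mean over points of `(b−a)/max(a,b)`; singleton points
  contribute 0 (sklearn's convention, adopted deliberately); undefined (NaN)
  when there is one cluster or every cluster is a singleton.  Asserted equal
  to a direct per-point evaluation to 1e-12.
* **Within-cluster correlation.**  One *pooled* Pearson over the union of
  within-cluster pairs per (dimension, height, scope) — not an average of
  per-cluster correlations — so the statistic at height 100% equals the
  lexicon-wide pairwise result exactly (asserted in the tests).  Records
  with fewer than 3 within-cluster pairs carry an undefined correlation.
* **Memory.**  The sweep holds full n×n similarity matrices per scope
  (~30 MB each at n ≈ 2000), trading memory for a fast 100-height grid; the
  pairwise module's streaming path is the reference for larger lexicons.

## Synthetic generator

The generator emulates what the clustering analysis presumes real lexicons
contain: semantically coherent neighborhoods whose members share formational
material.

* Semantic side: `K` cluster centers drawn i.i.d. `N(0, σ_b² I_d)`, signs at
  `center + σ_w ε`, `ε ~ N(0, I_d)`.  Defaults `d = 100`, `σ_w = 0.5`,
  `σ_b = 2.0` give well-separated clusters whose within-cluster cosine
  fluctuations are still informative — cluster-mate cosines around 0.9,
  cross-cluster around 0.
* Phonological side: each cluster draws one canonical label per slot; slot
  inventories default to sizes a field practitioner would recognize
  (handshape slots 30 labels, location 20, movement 12/10/6/6).  In coupled
  scopes a sign adopts the canonical label with probability `ρ^(4t)`,
  `t = chi2.cdf(‖ε‖², d)` the sign's semantic-displacement percentile
  (uniform by construction); otherwise, and always in uncoupled scopes, the
  label is uniform over the inventory.
* Why prototypicality-dependent adoption: with a flat adoption probability,
  label draws are independent of the semantic noise, so *within* a cluster
  the two similarity fluctuations are uncorrelated and the pooled
  within-cluster r is ~0 at every ρ — there would be nothing for the
  within-cluster analysis to recover, and no within-versus-lexicon-wide
  contrast to demonstrate.  Tying adoption to semantic centrality is the
  minimal mechanism that plants a recoverable within-cluster correlation
  while preserving the limits: ρ = 0 gives uniform labels (null), ρ = 1
  gives fully canonical forms (within-cluster phonological similarity
  exactly 1).  The exponent 4 was chosen at design time, by simulation, as
  the smallest integer for which the implied correlation is monotone over
  ρ = 0.2 → 0.8 (smaller exponents flatten and then invert above ρ ≈ 0.6 as
  adoption variance collapses).
* The implied correlation has no closed form and is never asserted
  analytically; `planted_effect` estimates it by Monte Carlo using the
  *true* labels and raw one-hot cosines, independent of the clustering path
  the pipeline must take.
* Glosses are generated tokens (`s0001`, ...) and the embedding table is
  written in GloVe text format, so synthetic runs exercise the real readers
  end to end.

What the generator does not emulate: real phonotactics (slot labels are
exchangeable and slots independent given the cluster), real GloVe geometry
(anisotropy, frequency effects, polysemy), missing slots, or cross-language
structure.  Passing the synthetic benchmark therefore shows the *pipeline*
is unbiased and calibrated under the planted model, not that any particular
real lexicon satisfies that model.

## Validation problem sizes

The test suite and acceptance script validate at sizes chosen to make
Monte-Carlo error small relative to the tolerances while keeping runs
desk-scale: oracle equivalence on 100 random Ward instances (n ≤ 40) and
silhouette instances up to n = 200; parameter recovery over 200 replicates
per ρ ∈ {0, 0.3, 0.6} at n = 300, K = 10 (recovered mean within ±0.03 of
the oracle; the standard error of each mean is ≈ 0.004); and the contrast
fixture at n = 1,950, K = 60, ρ = 0.5 coupled to movement only, where the
silhouette profile must peak in the interior of the height grid and the
pooled within-cluster r at the generative granularity must exceed the
lexicon-wide r, with the uncoupled scopes non-significant.

## Known limitations

* Cosine on one-hot blocks sees only exact label matches; gradient
  similarity between handshapes (joint-flexion distance and the like) is out
  of scope by design.
* The Pearson t-test over overlapping pairs is mildly anti-conservative in
  principle; calibration is verified empirically under the null rather than
  corrected analytically (a Mantel-style permutation test would be the
  rigorous alternative and is a natural extension).
* Embedding choice is the user's: the pipeline treats the embedding file as
  ground truth for meaning, inheriting whatever biases it carries (including
  the use of spoken-language embeddings for sign glosses).
* At ρ near 1 the planted-effect oracle degenerates (within-cluster
  phonological similarity approaches a constant and r is undefined in the
  limit); the benchmark therefore operates at moderate ρ.
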