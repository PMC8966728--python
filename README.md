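# formsem

Vector-space analysis of form–meaning correspondence in sign-language
lexicons.

## The scientific problem

Sign-language vocabularies are rich in non-arbitrary signs: forms that
resemble their referents (iconicity, e.g. verbs of cognition articulated on
the head) or that share formational material with semantically related signs
by language-internal convention (systematicity, e.g. sign families sharing a
handshape).  A lexicon-scale question follows: do signs that are close in
*meaning* tend to be close in *form*, and if so, at what granularity of the
lexicon does the relationship live — across all sign pairs, or concentrated
inside semantically coherent neighborhoods?

`formsem` answers this quantitatively for any lexicon that provides

1. a per-sign table of categorical phonological annotations over twelve
   slots — handshape and location for the dominant and non-dominant hand at
   the beginning and end of each sign, plus local movement, path movement,
   axis and non-dominant-hand behavior; and
2. a pre-trained word-embedding file in GloVe plain-text format supplying a
   semantic vector per gloss.

It is aimed at sign-language linguists and computational psycholinguists who
want reproducible, lexicon-wide estimates of form–meaning systematicity, and
at methodologists who want a tested reference pipeline with a synthetic
benchmark whose ground truth is known.

## The method

**Spaces.**  Each sign *s* gets a phonological vector by one-hot encoding its
slot labels within a parameter scope (handshape, location, movement, or all
twelve slots, "entire"), reduced by truncated SVD to its coordinates
`u_s = U_k Σ_k` (full-rank mode recovers the raw encoding exactly).  Its
semantic vector `v_s` comes from the embedding table; signs without an
embedding are dropped.  All similarities are cosines,
`cos(x, y) = x·y / (‖x‖‖y‖)`.

**Pairwise analysis.**  Over all `n(n−1)/2` unordered pairs, the association
between semantic similarity and phonological similarity per scope is the
Pearson correlation `r`, tested two-sided via `t = r√(df/(1−r²))`,
`df = n_pairs − 2` (α = 0.001 by default).  For n = 1,946 aligned signs this
is 1,892,485 pairs and df = 1,892,483; the computation streams over row
blocks so the pair set is never materialized.

**Clustering analysis.**  The semantic vectors are clustered agglomeratively
with Ward's minimum-variance criterion on Euclidean distance.  The dendrogram
is cut at pruning heights 1–100% of the maximum merge height; each flat
solution is scored with the mean silhouette `(b−a)/max(a,b)`, and the
correlation is recomputed using only pairs that do not cross cluster
boundaries, pooled over clusters into one Pearson `r` per scope and height.
The silhouette profile identifies the heights at which the semantic space is
best organized; comparing the pooled within-cluster `r` there against the
lexicon-wide `r` shows whether form–meaning correspondence is concentrated
inside semantic neighborhoods.

**Synthetic benchmark.**  A seeded generator plants `K` Gaussian semantic
clusters and couples the categorical annotations to them: each cluster has
canonical labels, and a sign adopts its cluster's canonical label at each
coupled slot with probability `ρ^(4t)`, where `t` is the percentile of the
sign's semantic displacement from its cluster center.  Semantically central
signs are thus also phonologically canonical, planting a recoverable
within-cluster correlation that is zero at ρ = 0 and grows with ρ.  The
implied correlation is estimated by the Monte-Carlo oracle
`planted_effect`, against which the full estimation pipeline is validated.

## Worked example

Generate a synthetic lexicon of 1,950 signs in 60 semantic clusters whose
movement annotations (only) are coupled to meaning at ρ = 0.5, then run both
analyses:

```bash
cat > fixture.yaml <<EOF
n_clusters: 60
cluster_sizes: [33, 33, ... , 32]   # 30 x 33 and 30 x 32 signs
coupling: 0.5
coupled_scopes: [movement]
seed: 42
EOF
formsem synth   --config fixture.yaml --out syn
formsem pairwise --lexicon syn/lexicon.tsv --embeddings syn/embeddings.txt \
                 --dim 100 --out pairwise
formsem sweep    --lexicon syn/lexicon.tsv --embeddings syn/embeddings.txt \
                 --heights 1:100:1 --out sweep
```

The pairwise step prints the lexicon-wide correlations:

```
handshape: r(1900273) = 0.0017, p = 0.0203 (NS at alpha=0.001)
location: r(1900273) = -0.0005, p = 0.505 (NS at alpha=0.001)
movement: r(1900273) = 0.0569, p = 0 (significant at alpha=0.001)
entire: r(1900273) = 0.0508, p = 0 (significant at alpha=0.001)
```

Only the coupled parameter (movement) shows a lexicon-wide association, and
it is weak (r ≈ 0.06).  `sweep/silhouettes.csv` peaks at pruning height 5%
(silhouette 0.720, 60 clusters — exactly the planted granularity), and
`sweep/sweep.csv` at that height shows the within-cluster correlations:

```
movement   within r=+0.1914 p=2.07e-251 sig=True  n=30720
handshape  within r=+0.0006 p=0.915     sig=False n=30720
location   within r=-0.0003 p=0.951     sig=False n=30720
```

The form–meaning relationship is three to four times stronger inside
semantic clusters than lexicon-wide, and confined to the coupled parameter —
the qualitative signature this pipeline is designed to detect, with the
uncoupled parameters serving as built-in negative controls.

To analyze a real lexicon, point `--lexicon` at a TSV/CSV with a `gloss`
column and any subset of the twelve slot columns, and `--embeddings` at a
GloVe text file (100/200/300-dimensional); entries are deduplicated to their
first listed variant before analysis, and `formsem inspect --glosses ...`
extracts the clusters containing given glosses for post-hoc inspection.

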