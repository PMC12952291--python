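# Methods

## Retrieval model

`geosift` treats dataset discovery as ranked retrieval against a
reference set. A document is the concatenation of a series' title,
summary, and overall design (in that order, empty fields skipped).
Cleaning applies, in a fixed order: HTML-tag stripping, URL removal,
lowercasing, replacement of non-alphanumeric characters with spaces,
whitespace collapsing, whitespace tokenization, stop-word removal, and
Porter stemming — each step gated independently by a `CleaningPolicy`
flag. The order is a package choice (the steps themselves are standard,
their order rarely stated anywhere); it is fixed so that cleaning is
idempotent whenever stemming is off, which the test suite verifies by
property. Non-alphanumeric characters are replaced by spaces rather than
deleted so that slash- or hyphen-joined terms ("TNBC/ER-") split into
separate tokens instead of fusing. URLs are recognised as
scheme-prefixed (`http`/`https`/`ftp`) or `www.`-prefixed substrings up
to the next whitespace. The stop-word list is a fixed English list
bundled as a data file, so results cannot drift with a third-party
package release; stemming is the classic Porter algorithm, implemented
in `_porter.py` and tested against the algorithm's published reference
vocabulary pairs.

For vector backends the query is the unweighted mean of the reference
documents' embeddings and candidates are ranked by cosine similarity,
which is scale-invariant per vector; cosine against a zero vector is
defined as 0 and empty-cleaning candidates are kept with score 0 and
flagged. Ties are broken by ascending accession so rankings are
deterministic and permutation-invariant. Candidates that appear in the
reference set are excluded before ranking.

The frequency baselines need a reference aggregation of their own (an
average "document" is not defined for them): **word_overlap** scores each
candidate by the Jaccard index against the pooled unique-token set of all
reference documents, and **bm25**/**bm25plus** build the index over the
candidates and use the concatenated reference token stream as the query.
Both aggregations are deliberate extensions of the single-pair
similarity; they keep the reference-set interface uniform across
backends. A consequence worth knowing: when reference documents are long
and dominated by background vocabulary, the pooled Jaccard query dilutes
the condition signal, so word_overlap degrades sharply at extreme
imbalance — visible in the acceptance output.

## BM25 (lucene variant)

score(q, d) = Σ_{t∈q} idf(t) · f(t,d) / (f(t,d) + k₁(1 − b + b·|d|/avgdl)),
idf(t) = ln(1 + (N − df(t) + 0.5)/(df(t) + 0.5)).

Defaults k₁ = 1.5, b = 0.75, the common defaults for this variant. The
two application modes mirror how the baseline is used in practice:
`bm25` on text cleaned without stop-word removal or stemming, `bm25plus`
with both. The index constructor enforces this contract, and
`rank_by_reference` coerces the policy's two flags to match the requested
mode so callers cannot silently mix them; the effective policy is
recorded in output manifests.

## Hashed TF-IDF stand-in embedder

A deterministic vector backend: each token is hashed (64-bit FNV-1a,
fixed constants, platform-independent) to a bucket in [0, dim) with a
sign bit; buckets accumulate tf · ln((N+1)/(df+1)) with document
frequencies taken from the candidate corpus; the vector is
L2-normalised unless all-zero. Default dim = 256, enough that disjoint
ten-token documents are nearly orthogonal (mean |cos| ≈ 0.03 over seeded
draws) while keeping the benchmark fast. Two caveats are inherent to the
construction: sign collisions can occasionally push |cos| between
disjoint documents to ~0.3, and in a single-document corpus every idf
weight is zero, so the embedding is the zero vector. This backend exists
so that the retrieval and evaluation machinery is exercisable offline;
external neural embeddings plug in through the vector-table adapter and
are out of scope to run here.

## Chunking

Texts longer than 256 characters may be split into 256-character windows
overlapping by 20 characters; window vectors are mean-pooled. The chunk
length reuses the 256-character threshold (the minimal-assumption
choice), boundaries are character-exact (the thresholds are
character-based, so word-aware splitting would change the unit), and the
mean is unweighted; per-chunk L2 normalisation before averaging exists
behind a flag, off by default, since cosine is scale-invariant per
vector but the mean is not. Reconstruction of the input from its chunks
(dropping each later chunk's leading overlap) is exact and
property-tested.

## Benchmark protocol

Per condition, the annotated accessions are sorted, permuted uniformly
under a seed, and split: first ⌈n/2⌉ to the reference set (the odd extra
goes to the reference), rest to comparison set A. Comparison set B is
every other series in the labeled universe — series annotated for other
conditions count as irrelevant. Imbalance ratio r subsamples B to
r · |A| accessions without replacement; "all" keeps the full pool.

AUPRC is computed as average precision — the mean over relevant entries
of precision at their ranks — with no trapezoidal interpolation: AP is
ranking-native, estimator-free, and checkable by exhaustive enumeration,
which the tests do for every label pattern up to length 12 against an
independent implementation. Recall@n is the fraction of all relevant
entries in the top n. For a uniformly random ranking the expected AP is
*not* the prevalence at small sample sizes: with 5 relevant among 55 the
exact expectation (computable from the rank distribution of the j-th
relevant item) is 0.151 versus a prevalence of 0.091; the excess decays
as the list grows at fixed class balance. The test suite checks the
Monte-Carlo mean against the exact expectation and the decay of the
excess, rather than asserting the asymptotic identity at a size where it
does not hold.

Cross-condition aggregation ranks backends within each condition by
descending AUPRC (average ranks for ties) and reports each backend's
median rank. The benchmark driver runs the full factorial of conditions
× backends × ratios × chunking settings; each cell derives split and
subsample seeds by hashing the master seed with the cell key (SHA-256,
truncated below 2³¹), so any cell is reproducible in isolation. A
consequence is that different backends see different random splits of
the same condition; cells are comparisons of distributions over splits,
not paired on one split.

## Synthetic corpus generator

The generator emulates the structure that makes metadata retrieval hard:
condition-specific terminology embedded in generic prose of highly
variable length. Each condition owns a vocabulary of pseudo-words
(pronounceable consonant-vowel syllables from a seeded generator — no
real vocabulary is copied); every document draws each token from the
condition vocabulary with probability `condition_token_rate` and from a
shared background vocabulary otherwise; distractor series draw
background tokens only. The token stream is partitioned ~10/60/30% into
title/summary/overall-design. Cross-condition confusability is
controlled by a common *confusion pool* included in every condition's
vocabulary at exactly the `cross_condition_overlap` fraction; a
pool gives an exact, monotone pairwise shared fraction for any number of
conditions, whereas mutual borrowing between neighbours degenerates at
full overlap into swapped (disjoint!) vocabularies. `degrade_corpus`
injects removable noise — HTML tags, URLs, random casing with attached
punctuation (the punctuation rides on the casing rate; both are
character-level, removable perturbations) — so that degrade-then-clean
reproduces the pristine token multisets, a round-trip the tests assert
end-to-end through ranking.

Defaults are fixed once to mirror a realistic curated universe: six
conditions with 12, 24, 30, 34, 109, and 121 annotated series plus 5,667
distractors (a 5,997-series labeled universe, ~1000:1 imbalance for the
smallest condition at full pool); 40-token condition vocabularies over a
500-token background; overlap 0.2; condition token rate 0.25 (condition
terms are a minority of real descriptions); document lengths uniform in
60–300 tokens (short abstract to long design paragraph). What the
generator does **not** emulate: grammatical prose, topical correlation
between background tokens, series with multiple condition labels,
platform/species diversity (fixed filler values chosen to pass the
ingest filter), and annotation noise. Passing recovery tests therefore
demonstrates correctness of the retrieval and evaluation machinery, not
expected performance of any backend on real repository text.

## Numerical and degenerate-input choices

- Cosine, word overlap with empty union, and BM25 with absent query
  tokens all return 0 rather than erroring; empty cleaned documents are
  flagged and scored 0.
- AUPRC requires at least one relevant and one irrelevant labelled entry
  and fully known labels; recall@n of a list with no relevant entries
  is 0.
- Chunking requires threshold ≤ chunk size when enabled (texts between
  the two would otherwise escape chunking) and overlap < chunk size.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are SHA-256-based and kept below 2³¹.

## Problem sizes

The default test-suite corpora are small (tens of series, 10–40-token
documents); the acceptance script uses the full 5,997-series default
universe for the headline benchmark and 76-series corpora for the
20-seed × 3-level overlap sweep. These sizes are the package's choices
for routine runs; all generators accept larger configurations unchanged.

## Known limitations

- The benchmark's per-cell splitting means backend comparisons are not
  paired on identical splits (see above).
- The pooled-reference word-overlap query dilutes signal for long
  reference sets; scoring candidates against each reference document and
  aggregating (e.g. max) would be a reasonable alternative surface.
- The SOFT reader covers only the `^SERIES`/`!Series_*` attribute subset
  needed for the record fields; platform vendor and retirement status are
  not present in that subset and default to empty/false, so SOFT-sourced
  records typically need the JSON-lines dialect for filtering fidelity.
- `bm25plus` stems pseudo-words too; on synthetic corpora stemming is a
  no-op in the common case but can occasionally merge distinct
  pseudo-words.
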