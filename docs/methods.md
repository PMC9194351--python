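# Methods

This note records the modeling choices behind `sentinelnet`, the defaults
and why they were chosen, the study conditions the synthetic generator
emulates, and the package's known limitations.

## Data model and activity accounting

A corpus is a line-delimited JSON stream of tweet records (id, account,
timestamp, text, optional original-poster id for retweets, list of URLs).
Day bucketing uses a single configurable timezone (default UTC) through
every stage; analyses demarcated in US Eastern time require
`day_boundary_tz="America/New_York"`. Deleted tweets are simply absent
records — no tombstone handling.

Sentinel accounts disappear over a monitoring period (deletion,
suspension). To normalize tweet rates for this attrition, an account is
*active* on a day if it tweets on that day **or any later day** of the
window, so its *active account days* equal the span from the window start
through its last observed tweet. This deliberately counts silent-but-alive
days as active: an account that tweets sparsely is still being monitored.

Inter-coder reliability of a human coding exercise is summarized by
Krippendorff's alpha (nominal metric, coincidence-matrix formulation).
Units with fewer than two non-missing codes are dropped; a matrix whose
recorded codes are all identical has zero expected disagreement and
returns 1.0 with a warning — the conventional reading of "nothing to
disagree about".

## Retweet network and communities

Edges point retweeter → original poster with multiplicity weights, so a
node's weighted in-degree counts how often it was retweeted. "Largest
connected component" is read in the **weak** sense: retweet graphs are
near-acyclic, and strong components would be trivially small. Size ties
break toward the lexicographically smallest node set, so the choice is
deterministic.

Directed weighted modularity uses the in/out-degree null model, including
the diagonal i = j null terms (the graph itself has no self-loops).
Optimization is greedy multilevel ("Louvain") on the **symmetrized**
modularity matrix (B + Bᵀ)/2 — the standard treatment of directed
modularity by generalized-Louvain implementations, and exactly equivalent
in objective value because the partition indicator is symmetric. Node
visitation order is shuffled once per sweep from the seed; moves require a
gain above 1e−10; 5 restarts keep the best partition; a given seed is
bit-reproducible. The resolution parameter defaults to 1 (plain
modularity) but is exposed. The dense-matrix implementation is appropriate
for the network sizes a sentinel design targets (10²–10⁴ nodes after
component extraction at desk scale); it is not intended for multi-million
node graphs.

Sentinel selection takes the k = 15 most-retweeted nodes per community
(fewer for smaller communities), with lexicographic tie-breaks, after
dropping communities below a minimum size; an injectable predicate can
screen communities (e.g. by language or locality) and defaults to
pass-through. The per-community in-degree coverage of the top-k nodes is
reported with mean/median/IQR.

Partition stability uses the Rand index and the z-Rand score. The z-Rand
null fixes both partitions' group sizes and permutes node assignments; its
exact closed-form mean and variance are implemented (the variance includes
the third-moment pair-dependence terms, not merely the naive pair-level
hypergeometric approximation, which would be biased). The closed form was
verified against a large node-permutation simulation before being frozen
into tests. Degenerate nulls (zero variance) report z as missing.

## Linked-domain characterization

URLs normalize to lowercased registered domains with a small embedded
table of common multi-label public suffixes (co.uk, com.au, …);
twitter.com and a configurable list of URL shorteners are tagged and
excluded from the matrix but counted in the accounting report, which
satisfies the conservation identity all = twitter + shortened + retained.
Retained links whose domain cannot be parsed are counted but excluded from
matrix columns.

The community × domain matrix keeps domains shared at least `min_total`
(default 10) times **across all communities**; a per-community variant of
the threshold is available behind a flag since both readings of a
"shared ≥ 10 times" rule are defensible. Row fractions are renormalized
over qualifying columns so each nonempty row sums to 1, making communities
with different twitter/shortener mixes comparable.

PCA centers columns but does **not** scale to unit variance: the rows are
compositions, and unit-variance scaling would inflate rare domains. The
sign of the first component is arbitrary, so orientation is fixed by an
anchor domain forced to a positive loading (default: the largest-magnitude
loading); to obtain a "conservative pole positive" orientation, anchor on
a conservative outlet's domain.

Scores are clustered by agglomerative clustering on the 1-D scores.
Centroid linkage is the default and average ("mean") linkage is available
behind a flag — the two descriptions appear in different places in the
literature this design follows, and on 1-D data they rarely differ; the
package does not silently reconcile them. Every cut from 2 to `max_k`
clusters is scored by silhouette; the best cut is kept unless the user
forces a specific k (analysts sometimes prefer a finer cut than the
silhouette optimum when clusters are substantively distinct). Degenerate
cuts (duplicate scores) are skipped with a warning.

An optional media-bias table (CSV `domain,category`, MBFC-style categories)
joins loadings to categories, reporting per-category loading
distributions, the match rate, and the Pearson correlation between loading
and the Left(1)…Right(5) ordinal.

## Topics and rates

Topic membership is plain lowercase substring containment — "mask" matches
"masks" and "unmasked" alike. That bluntness is faithful to how the
surveillance keyword lists are defined; a word-boundary mode exists behind
a flag. Topics nest: a child matches only within its parent's matches, with
the COVID gate ("covid", "coronavirus", "sars-cov", "pandemic") at the
root. Keyword lists ship as editable text files; the severity, downplaying,
hesitancy and vaccine-misinformation lists are partial reconstructions
around the documented example phrases and are marked as such in the files.

Per-capita rates divide topical tweet counts by active account days;
scaled rates divide by the cross-community sum so they total 1. A display
normalization (daily tweets per 15 active accounts) supports time-series
plots. The stratified sampling scaffold draws up to n (default 100) tweets
per (cluster, topic) stratum with communities represented as equally as
possible: equal quotas with largest-remainder rounding, and quotas
exceeding a community's supply re-allocated among the rest to a fixed
point. Chi-square tests on coded contingency tables are Pearson's without
continuity correction (the uncorrected statistic is what the reconstructed
worked examples reproduce); percentage→count reconstruction rounds to the
nearest integer per cell.

## Burst detection and attribution

Documents are per community-day: cleaning lowercases, strips URLs and
@mentions, tokenizes on word characters, and drops a fixed shipped English
stopword list; trigrams are consecutive word triples within a tweet,
never spanning tweets. Cosine similarity of two count vectors lies in
[0, 1]; an empty document yields similarity 0 (flagged), never an
exception. Cluster-pair similarity is the arithmetic mean over all
(a ∈ A, b ∈ B) community pairs; a within-cluster diagnostic over unordered
distinct pairs is also available.

The burst score standardizes today's similarity against the **expanding**
history of all observed prior days — not a rolling window — because the
baseline period is meant to seed a stable historical reference. The SD is
the sample standard deviation (ddof = 1; configurable). A history that is
constant up to floating-point rounding (SD ≤ 1e−12 relative) is reported
as missing rather than ±∞. Flagging requires H ≥ 2 and skips the first 7
days (burn-in); both are configurable. An augmented Dickey-Fuller check
(constant-only, 0 lag) is logged as a stationarity diagnostic before
flagging but does not block it.

LSA attribution builds the tweet × trigram matrix of each flagged
cluster, takes the truncated SVD, and for each of the top 5 document
singular vectors sorts component magnitudes and cuts at the largest ratio
between consecutive magnitudes (scanned over the leading 50 positions,
minimum one tweet) — a deterministic formalization of "a sharp drop",
since the drop is otherwise in the eye of the beholder; the cut rule and
the component count are configurable. Component signs are ignored
(singular-vector sign is arbitrary). "Common to both clusters" is
formalized as near-duplicate pairs across the two topical sets (trigram
Jaccard ≥ 0.5 by default, configurable) because virally shared content
recurs nearly verbatim. Removal recomputes the day's similarity and burst
score against the unchanged history; a flag is *attributed* iff the
recomputed score falls below the threshold.

## Synthetic study conditions

The generator emulates the statistical regime the pipeline assumes, with
defaults chosen once as the test-bed conditions: 4 communities × 25
accounts; 3,000 retweets with within-community probability p_in = 0.95 and
targets drawn by preferential attachment on in-degree (heavy-tailed
in-degrees, as the sentinel-coverage statistic assumes); 42 days of
content at ~2 tweets per account-day; background tokens drawn from a
community-permuted Zipf vocabulary of 2,000 words so baseline
cross-community trigram overlap is tiny; a COVID gate token in 90% of
tweets; links in ~25% of tweets drawn from community-specific preferences
over a 12-domain pool split into two planted poles, plus small twitter.com
and shortener shares; and verbatim planted event texts on known days.

Cross-community baseline similarity comes from a "story of the day": one
shared phrase inserted into a fixed number of tweets per community per
day, cycling through a deterministic weekly news-volume pattern
(6,6,6,6,5,3,3). This gives the near-zero but non-degenerate baseline the
burst score needs, with bounded day-to-day fluctuation — mimicking the
weekday/weekend periodicity of news-driven posting rather than free
Gaussian noise, whose unbounded tails would routinely produce 2σ days by
chance in any short series.

What passing these conditions shows: the estimators recover planted
community structure, domain poles, and virality events under assortative,
heavy-tailed, low-overlap conditions. What it does not show: performance
on real platform data with multilingual text, bot traffic, topic drift,
overlapping community membership, or adversarial near-duplicates — none of
which the generator models (its text is template-based, not natural
language).

## Numerical choices and degenerate inputs

- Ties: argmax ties resolve to the lowest index (Louvain moves), in-degree
  ties to the lexicographically smaller account id (sentinels), silhouette
  ties to the smaller k (cut selection).
- All randomness flows through `numpy.random.default_rng` seeded from
  named integer seeds; per-stratum sampling seeds derive from a CRC of the
  stratum key, never from Python's salted `hash`.
- Empty networks, partitions missing nodes, zero-margin contingency
  tables, sub-minimum LSA corpora, and windows with no observations raise
  `ValueError` with explicit messages; recoverable degeneracies (all-equal
  scores, constant similarity histories, zero-variance nulls, all-zero
  rates) return flagged missing values with warnings instead.
- Problem sizes in tests and the acceptance script (n = 100-node planted
  graphs, 30-day monitoring series, 10,000-unit reliability simulations,
  10,000-permutation nulls) were chosen so each check runs in seconds
  while leaving Monte-Carlo error well inside the asserted tolerances.

## Limitations

- The Louvain implementation is dense-matrix; beyond ~10⁴ nodes a sparse
  implementation would be needed.
- Substring topics are deliberately crude: no stemming, stance, or
  negation handling; counts measure engagement with a vocabulary, not
  endorsement of a claim.
- Trigram cosine captures lexical overlap only; paraphrase without shared
  wording is invisible (embedding-based similarity is out of scope).
- Attribution identifies near-duplicate topical content consistent with
  driving a burst; it is not a causal diffusion-path reconstruction, and
  the sentinel design intentionally trades cascade detail for coverage.
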