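# sentinelnet

Sentinel-node surveillance of topical (mis)information spread across online
communities.

Monitoring everything posted about a topic on a large platform is expensive
and noisy. `sentinelnet` implements a data-light alternative borrowed from
epidemiological sentinel surveillance: detect communities in a retweet
network, follow only a small set of *sentinel accounts* (the most-retweeted
members of each community), characterize communities by the news domains
they link to, and watch for days on which textual similarity between
community clusters bursts above its historical baseline — the signature of
content jumping across otherwise separate audiences. It is aimed at
computational social scientists and infodemiology / digital-epidemiology
researchers who need to triage which narratives are spreading beyond their
community of origin.

## The model

**Communities.** The retweet network is a weighted directed graph with
A<sub>ij</sub> = number of times account *j* retweeted account *i* (self-retweets
excluded). On its largest weakly connected component, communities maximize
the directed, weighted modularity

```
Q = (1/w) Σᵢⱼ ( Aᵢⱼ − wᵢⁱⁿ wⱼᵒᵘᵗ / w ) δ(Cᵢ, Cⱼ)
```

with *w* the total edge weight and w<sup>in</sup>/w<sup>out</sup> the weighted in/out
degrees. Optimization is a greedy multilevel (Louvain-type) algorithm run on
the symmetrized modularity matrix (B + Bᵀ)/2. Partition stability across
collection periods is measured by the Rand index and the z-Rand score
(standardized count of co-assigned pairs under the hypergeometric
permutation null).

**Sentinels.** From each sufficiently large community, the k = 15 accounts
with the largest weighted in-degree (most retweeted) are the sentinels; the
in-degree distribution is heavy-tailed, so a handful of accounts covers most
of a community's retweet volume.

**Linked-domain score.** Links shared by each community are normalized to
registered domains (twitter.com and URL shorteners excluded, rare domains
thresholded), forming a community × domain link-fraction matrix. Each
community's projection onto the first principal component is its *linked
domain score*; hierarchical (centroid-linkage) clustering of the 1-D scores,
with silhouette-guided cut selection, groups communities into clusters of
shared media preference.

**Burst detection.** For every community and day, the cleaned COVID-related
tweets form a document represented by word-trigram counts. The daily
similarity s<sub>t</sub>(A,B) between clusters A and B is the mean cosine
similarity over community pairs, and the burst score is the expanding-window
z-score

```
H(A,B,t) = ( s_t − mean_{τ<t} s_τ ) / SD_{τ<t} s_τ
```

Days with H ≥ 2 (after a 7-day burn-in) are flagged. On a flagged day,
latent semantic analysis over each cluster's tweet × trigram matrix surfaces
the *topical tweets* (sharp drops in the leading document singular vectors);
near-duplicate topical tweets present in both clusters are removed and H is
recomputed — if it falls below threshold, the burst is attributed to those
tweets.

## Worked example

Generate a synthetic corpus with 4 planted communities (two media "poles")
and a cross-cluster virality event planted on day 20, then run the full
pipeline:

```
$ sentinelnet simulate --out corpus.jsonl --seed 1 --days 30 --event-day 20
wrote 9134 tweets to corpus.jsonl

$ sentinelnet run --corpus corpus.jsonl --out run --seed 1 --min-size 5 --force-k 2
Q=0.7031; 2 flagged day(s); artifacts in run

$ sentinelnet report --run-dir run
corpus: corpus.jsonl (9134 tweets)
clusters: k=2 silhouette=0.996
flagged days: 2
  2020-07-18 pair=['0', '1'] H=2.32 attributed=False
  2020-07-21 pair=['0', '1'] H=15.79 attributed=True
```

Reading the output: community detection on the retweet network gives
modularity Q = 0.70 (four communities recovered); linked-domain PCA plus
clustering separates the two planted media poles perfectly (silhouette
0.996). Two days exceed the burst threshold: the planted event day
(2020-07-21, H = 15.8) is *attributed* — removing the near-duplicate topical
tweets found in both clusters drops the recomputed score below 2 — while the
marginal 2020-07-18 flag (H = 2.3) is a baseline fluctuation that attribution
correctly fails to pin on shared content. Artifacts (edge list, community
and cluster assignments, sentinel lists, domain scores, rate tables,
similarity series, flags with topical tweet ids) are plain CSV/TSV/JSON
under `run/`.

The same stages are available as library calls (`build_retweet_network`,
`LouvainCommunities`, `LinkedDomainPCA`, `DomainScoreClustering`,
`BurstDetector`, …) and as separate subcommands (`net`, `stability`,
`domains`, `topics`, `burst`).

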