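"""Inter-cluster content similarity, burst flagging, and attribution.

Each (community, day) pair defines a *document*: the cleaned text of that
community's COVID-related tweets for the day, represented as a vector of
word-trigram counts (trigrams never span tweet boundaries).  The daily
similarity between clusters A and B is the arithmetic mean of the cosine
similarities over all community pairs (a in A, b in B).  A day is flagged
when its burst score

    H(A, B, t) = (s_t - mean_{tau<t} s_tau) / SD_{tau<t} s_tau

is at least the threshold (default 2), where mean and SD run over all
observed days strictly before t (expanding history; sample SD, ddof=1) and
the first days of the window are reserved as burn-in.  For a flagged day,
latent semantic analysis over the tweet x trigram matrix of each cluster
surfaces the *topical tweets*; near-duplicate topical tweets common to both
clusters are removed and the burst score recomputed — if it falls below the
threshold, the flag is attributed to those tweets.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.tsa.stattools import adfuller

from .corpus import ObservationWindow, TweetRecord
from .topics import TopicRegistry, matches_topic

__all__ = [
    "load_stopwords",
    "clean_text",
    "tweet_trigrams",
    "cosine_similarity",
    "trigram_jaccard",
    "DailyDocument",
    "build_daily_documents",
    "daily_cluster_similarity",
    "similarity_series",
    "burst_score",
    "burst_scores",
    "BurstFlag",
    "flag_bursts",
    "BurstDetector",
    "stationarity_check",
    "lsa_topical_tweets",
    "attribute_burst",
    "write_similarity_series",
]

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.co/\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def load_stopwords() -> frozenset[str]:
    """Fixed English stopword list shipped with the package."""
    text = (resources.files("sentinelnet") / "data" / "stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


_STOPWORDS = None


def clean_text(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercase, strip URLs and @mentions, tokenize, drop stopwords."""
    global _STOPWORDS
    if stopwords is None:
        if _STOPWORDS is None:
            _STOPWORDS = load_stopwords()
        stopwords = _STOPWORDS
    s = _MENTION_RE.sub(" ", _URL_RE.sub(" ", text.lower()))
    return [tok for tok in (_t.strip("'") for _t in _TOKEN_RE.findall(s))
            if tok and tok not in stopwords]


def tweet_trigrams(tokens: Sequence[str]) -> Counter:
    """Counts of consecutive word triples; < 3 tokens contribute nothing."""
    return Counter(
        (tokens[i], tokens[i + 1], tokens[i + 2]) for i in range(len(tokens) - 2)
    )


def cosine_similarity(v1: Mapping, v2: Mapping) -> float:
    """Cosine of two sparse nonnegative count vectors; 0 if either is empty."""
    if not v1 or not v2:
        return 0.0
    if len(v2) < len(v1):
        v1, v2 = v2, v1
    dot = sum(c * v2[k] for k, c in v1.items() if k in v2)
    if dot == 0:
        return 0.0
    n1 = np.sqrt(sum(c * c for c in v1.values()))
    n2 = np.sqrt(sum(c * c for c in v2.values()))
    return float(dot / (n1 * n2))


def trigram_jaccard(v1: Mapping, v2: Mapping) -> float:
    """Jaccard similarity of trigram supports; 0 when both empty."""
    s1, s2 = set(v1), set(v2)
    if not s1 and not s2:
        return 0.0
    return len(s1 & s2) / len(s1 | s2)


# ---------------------------------------------------------------------------
# documents


@dataclass
class DailyDocument:
    """One community-day: cleaned tweets and their trigram vectors."""

    community: Hashable
    day: date
    tweet_ids: list[str] = field(default_factory=list)
    tweet_vectors: list[Counter] = field(default_factory=list)

    @property
    def vector(self) -> Counter:
        total: Counter = Counter()
        for v in self.tweet_vectors:
            total.update(v)
        return total

    def without(self, tweet_ids: set[str]) -> "DailyDocument":
        keep = [i for i, tid in enumerate(self.tweet_ids) if tid not in tweet_ids]
        return DailyDocument(
            self.community,
            self.day,
            [self.tweet_ids[i] for i in keep],
            [self.tweet_vectors[i] for i in keep],
        )


def build_daily_documents(
    tweets: Iterable[TweetRecord],
    membership: Mapping[str, Hashable],
    window: ObservationWindow,
    registry: TopicRegistry | None = None,
    gate_topic: str = "covid",
    stopwords: frozenset[str] | None = None,
) -> dict[tuple[Hashable, date], DailyDocument]:
    """Bucket gated tweets into (community, day) trigram documents.

    When a registry is given, only tweets matching ``gate_topic`` enter the
    documents.  Tweets that clean to fewer than 3 tokens still count as
    members of the document but contribute an empty trigram vector.
    """
    docs: dict[tuple[Hashable, date], DailyDocument] = {}
    for t in tweets:
        c = membership.get(t.account_id)
        if c is None or not window.contains(t.timestamp):
            continue
        if registry is not None and not matches_topic(t.text, gate_topic, registry):
            continue
        day = window.day_of(t.timestamp)
        key = (c, day)
        if key not in docs:
            docs[key] = DailyDocument(c, day)
        docs[key].tweet_ids.append(t.tweet_id)
        docs[key].tweet_vectors.append(tweet_trigrams(clean_text(t.text, stopwords)))
    return docs


def _pair_key(a: Hashable, b: Hashable) -> tuple:
    return tuple(sorted((a, b), key=str))


def daily_cluster_similarity(
    vectors: Mapping[Hashable, Mapping],
    cluster_of: Mapping[Hashable, Hashable],
    include_within: bool = False,
) -> dict[tuple, float]:
    """Mean pairwise community cosine for each cluster pair on one day.

    ``vectors`` maps community -> trigram vector for the day; communities
    missing from it are treated as empty documents (cosine 0 with
    everything).  For A != B the mean runs over all (a in A, b in B) pairs;
    with ``include_within`` the within-cluster diagnostic uses unordered
    distinct pairs (a != b).
    """
    clusters: dict[Hashable, list[Hashable]] = {}
    for comm, cl in cluster_of.items():
        clusters.setdefault(cl, []).append(comm)
    labels = sorted(clusters, key=str)
    out: dict[tuple, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            sims = [
                cosine_similarity(vectors.get(ca, {}), vectors.get(cb, {}))
                for ca in clusters[a]
                for cb in clusters[b]
            ]
            out[_pair_key(a, b)] = float(np.mean(sims))
        if include_within:
            comms = clusters[a]
            if len(comms) < 2:
                out[(a, a)] = float("nan")
            else:
                sims = [
                    cosine_similarity(vectors.get(comms[i], {}), vectors.get(comms[j], {}))
                    for i in range(len(comms))
                    for j in range(i + 1, len(comms))
                ]
                out[(a, a)] = float(np.mean(sims))
    return out


def similarity_series(
    documents: Mapping[tuple[Hashable, date], DailyDocument],
    cluster_of: Mapping[Hashable, Hashable],
    window: ObservationWindow,
    include_within: bool = False,
) -> dict[tuple, pd.Series]:
    """Daily inter-cluster similarity series over the window, per pair."""
    days = window.days()
    cache = {key: doc.vector for key, doc in documents.items()}
    per_pair: dict[tuple, list[float]] = {}
    for day in days:
        vectors = {c: cache.get((c, day), Counter()) for c in cluster_of}
        sims = daily_cluster_similarity(vectors, cluster_of, include_within)
        for pair, s in sims.items():
            per_pair.setdefault(pair, []).append(s)
    idx = pd.Index(days, name="day")
    return {pair: pd.Series(v, index=idx, name=str(pair)) for pair, v in per_pair.items()}


# ---------------------------------------------------------------------------
# burst scoring


def burst_score(series: pd.Series, t, min_history: int = 2) -> float:
    """Burst score of day t against the expanding history of prior days.

    History is every observed (non-NaN) day strictly before t; the SD is the
    sample standard deviation.  NaN when there are fewer than
    ``min_history`` prior days, when s_t is unobserved, or when the
    historical SD is zero.
    """
    if t not in series.index:
        raise KeyError(f"day {t!r} not in series")
    st = series.loc[t]
    hist = series.loc[: t].iloc[:-1].dropna()
    if np.isnan(st) or len(hist) < min_history:
        return float("nan")
    sd = hist.std(ddof=1)
    # numerically zero SD (constant history up to rounding) is degenerate
    if np.isnan(sd) or sd <= 1e-12 * max(1.0, abs(hist.mean())):
        return float("nan")
    return float((st - hist.mean()) / sd)


def burst_scores(series: pd.Series, min_history: int = 2) -> pd.Series:
    """Vector of burst scores for every day of the series."""
    return pd.Series(
        [burst_score(series, t, min_history) for t in series.index],
        index=series.index,
        name="H",
    )


@dataclass
class BurstFlag:
    """A flagged day for one cluster pair, with attribution bookkeeping."""

    day: date
    pair: tuple
    h: float
    topical: dict = field(default_factory=dict)  # cluster -> {tweet_id: score}
    removed: list = field(default_factory=list)
    recomputed_similarity: float | None = None
    recomputed_h: float | None = None
    attributed: bool | None = None


def flag_bursts(
    series: pd.Series,
    pair: tuple = ("A", "B"),
    threshold: float = 2.0,
    burn_in_days: int = 7,
) -> list[BurstFlag]:
    """Days with H >= threshold, excluding the first ``burn_in_days``."""
    h = burst_scores(series)
    flags = []
    for i, t in enumerate(series.index):
        if i < burn_in_days:
            continue
        if np.isfinite(h.iloc[i]) and h.iloc[i] >= threshold:
            flags.append(BurstFlag(day=t, pair=tuple(pair), h=float(h.iloc[i])))
    return flags


class BurstDetector:
    """Expanding-window burst flagger over a similarity series.

    A thin estimator wrapper: :meth:`fit` stores the series and its burst
    scores; :meth:`predict` returns the flagged days.
    """

    def __init__(self, threshold: float = 2.0, burn_in_days: int = 7,
                 min_history: int = 2):
        self.threshold = threshold
        self.burn_in_days = burn_in_days
        self.min_history = min_history

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "burn_in_days": self.burn_in_days,
            "min_history": self.min_history,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.Series, y=None, pair: tuple = ("A", "B")):
        self.series_ = X
        self.scores_ = burst_scores(X, self.min_history)
        self.flags_ = flag_bursts(X, pair, self.threshold, self.burn_in_days)
        return self

    def predict(self, X: pd.Series | None = None) -> list[BurstFlag]:
        if X is not None:
            self.fit(X)
        return self.flags_


def stationarity_check(
    series: pd.Series, level: float = 0.05
) -> tuple[float, float, str]:
    """Augmented Dickey-Fuller diagnostic, constant-only model with 0 lag.

    Returns (statistic, p-value, verdict) where the verdict is
    'stationary' / 'non-stationary' at ``level``, or 'degenerate' for a
    constant series.  This is a logged diagnostic gate, not a hard stop.
    """
    x = np.asarray(series.dropna(), dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 observations")
    if np.allclose(x, x[0]):
        return float("nan"), float("nan"), "degenerate"
    stat, pval, *_ = adfuller(x, maxlag=0, regression="c", autolag=None)
    verdict = "stationary" if pval < level else "non-stationary"
    return float(stat), float(pval), verdict


# ---------------------------------------------------------------------------
# LSA attribution


def lsa_topical_tweets(
    tweet_ids: Sequence[str],
    tweet_vectors: Sequence[Mapping],
    n_components: int = 5,
    max_scan: int = 50,
) -> dict[str, float]:
    """Topical tweets via sharp drops in leading LSA document vectors.

    Builds the tweet x trigram count matrix, takes the truncated SVD, and
    for each of the top ``n_components`` document singular vectors sorts
    component magnitudes in descending order and cuts at the largest ratio
    between consecutive magnitudes (searched over the leading
    ``min(max_scan, n_docs)`` positions, minimum one tweet selected).
    Returns the union across components, with each tweet's best magnitude.
    Tweets with empty trigram vectors are excluded before the SVD.
    """
    keep = [i for i, v in enumerate(tweet_vectors) if v]
    if len(keep) < 2:
        raise ValueError("need >= 2 tweets with nonempty trigram vectors")
    ids = [tweet_ids[i] for i in keep]
    vecs = [tweet_vectors[i] for i in keep]
    vocab: dict = {}
    rows, cols, vals = [], [], []
    for r, v in enumerate(vecs):
        for tg, c in v.items():
            j = vocab.setdefault(tg, len(vocab))
            rows.append(r)
            cols.append(j)
            vals.append(float(c))
    x = sp.csr_matrix((vals, (rows, cols)), shape=(len(vecs), len(vocab)))
    k = min(n_components, min(x.shape) - 1)
    if k < n_components:
        warnings.warn(
            f"rank supports only {k} component(s), not {n_components}", stacklevel=2
        )
    if k < 1:
        raise ValueError("matrix rank too small for any component")
    if min(x.shape) <= 50:
        u, s, _ = np.linalg.svd(x.toarray(), full_matrices=False)
        u = u[:, :k]
    else:
        u, s, _ = sp.linalg.svds(x, k=k)
        order = np.argsort(s)[::-1]
        u = u[:, order]
    out: dict[str, float] = {}
    for comp in range(u.shape[1]):
        mags = np.abs(u[:, comp])
        order = np.argsort(-mags, kind="stable")
        m = mags[order]
        scan = min(max_scan, len(m)) - 1
        if scan < 1 or m[0] == 0:
            continue
        ratios = np.full(scan, -np.inf)
        for i in range(scan):
            if m[i] <= 0:
                break
            ratios[i] = np.inf if m[i + 1] == 0 else m[i] / m[i + 1]
        cut = int(np.argmax(ratios))
        for idx in order[: cut + 1]:
            tid = ids[idx]
            out[tid] = max(out.get(tid, 0.0), float(mags[idx]))
    return out


def _cluster_day_docs(
    documents: Mapping[tuple[Hashable, date], DailyDocument],
    cluster_of: Mapping[Hashable, Hashable],
    cluster: Hashable,
    day: date,
) -> dict[Hashable, DailyDocument]:
    comms = [c for c, cl in cluster_of.items() if cl == cluster]
    return {
        c: documents.get((c, day), DailyDocument(c, day)) for c in comms
    }


def attribute_burst(
    flag: BurstFlag,
    documents: Mapping[tuple[Hashable, date], DailyDocument],
    cluster_of: Mapping[Hashable, Hashable],
    series: pd.Series,
    threshold: float = 2.0,
    match_threshold: float = 0.5,
    n_components: int = 5,
) -> BurstFlag:
    """Remove-and-recompute attribution of a flagged day.

    Topical tweets are extracted per cluster by LSA; tweets *common to both
    clusters* are near-duplicate pairs across the two topical sets (trigram
    Jaccard >= ``match_threshold``).  Those are removed from both clusters'
    daily documents, the day's similarity and burst score recomputed against
    the unchanged history, and the flag marked attributed iff the
    recomputed score falls below the threshold.
    """
    a, b = flag.pair
    docs_a = _cluster_day_docs(documents, cluster_of, a, flag.day)
    docs_b = _cluster_day_docs(documents, cluster_of, b, flag.day)

    def _topical(docs: Mapping[Hashable, DailyDocument]) -> dict[str, float]:
        ids, vecs = [], []
        for d in docs.values():
            ids.extend(d.tweet_ids)
            vecs.extend(d.tweet_vectors)
        try:
            return lsa_topical_tweets(ids, vecs, n_components)
        except ValueError:
            return {}

    if not flag.topical:
        flag.topical = {a: _topical(docs_a), b: _topical(docs_b)}
    top_a, top_b = flag.topical[a], flag.topical[b]

    vec_by_id: dict[str, Mapping] = {}
    for d in list(docs_a.values()) + list(docs_b.values()):
        for tid, v in zip(d.tweet_ids, d.tweet_vectors):
            vec_by_id[tid] = v

    removed: set[str] = set()
    for ta in sorted(top_a):
        for tb in sorted(top_b):
            if trigram_jaccard(vec_by_id.get(ta, {}), vec_by_id.get(tb, {})) >= match_threshold:
                removed.add(ta)
                removed.add(tb)
    flag.removed = sorted(removed)
    if not removed:
        flag.recomputed_similarity = float(series.loc[flag.day])
        flag.recomputed_h = flag.h
        flag.attributed = False
        return flag

    vectors = {}
    for c, d in {**docs_a, **docs_b}.items():
        vectors[c] = d.without(removed).vector
    sims = daily_cluster_similarity(vectors, {c: cluster_of[c] for c in vectors})
    new_s = sims[_pair_key(a, b)]
    hist = series.loc[: flag.day].iloc[:-1].dropna()
    sd = hist.std(ddof=1)
    degenerate = np.isnan(sd) or sd <= 1e-12 * max(1.0, abs(hist.mean()))
    new_h = float("nan") if degenerate else float((new_s - hist.mean()) / sd)
    flag.recomputed_similarity = float(new_s)
    flag.recomputed_h = new_h
    flag.attributed = bool(np.isfinite(new_h) and new_h < threshold)
    return flag


def write_similarity_series(
    series: Mapping[tuple, pd.Series], path, scores: Mapping[tuple, pd.Series] | None = None
) -> None:
    """CSV export ``date,cluster_a,cluster_b,similarity,H``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("date,cluster_a,cluster_b,similarity,H\n")
        for pair in sorted(series, key=str):
            s = series[pair]
            h = scores[pair] if scores is not None else burst_scores(s)
            for day in s.index:
                fh.write(
                    f"{day},{pair[0]},{pair[1]},{s.loc[day]:.6g},{h.loc[day]:.6g}\n"
                )
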