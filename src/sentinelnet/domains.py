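"""Linked-domain characterization of communities.

Communities are characterized by the external web domains their accounts
link to.  The pipeline is: normalize each shared URL to its registered
domain (tagging twitter.com and URL shorteners for exclusion), form the
community x domain link-fraction matrix over domains shared at least
``min_total`` times, project communities onto the first principal component
of that matrix (the *linked domain score*), and cluster the 1-D scores
hierarchically, choosing a dendrogram cut by silhouette.

The sign of a principal component is arbitrary; orientation is fixed by an
anchor domain whose loading is forced positive (default: the domain with
the largest-magnitude loading).  To reproduce a "conservative pole
positive" orientation, anchor on a conservative outlet's domain.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping
from urllib.parse import urlsplit

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_score

from .corpus import TweetRecord

__all__ = [
    "DEFAULT_SHORTENERS",
    "NormalizedLink",
    "normalize_domain",
    "LinkAccounting",
    "build_domain_matrix",
    "LinkedDomainPCA",
    "DomainScore",
    "pca_first_component",
    "DomainScoreClustering",
    "ClusterAssignment",
    "cluster_scores",
    "join_bias_categories",
    "read_bias_table",
    "POLITICAL_ORDINAL",
]

DEFAULT_SHORTENERS = frozenset(
    {
        "bit.ly", "t.co", "ow.ly", "tinyurl.com", "goo.gl", "buff.ly",
        "is.gd", "dlvr.it", "trib.al", "ift.tt", "tiny.cc", "shorturl.at",
    }
)

# common multi-label public suffixes; the registered domain is one label
# deeper than the matched suffix
_MULTI_SUFFIXES = frozenset(
    {
        "co.uk", "org.uk", "gov.uk", "ac.uk", "me.uk", "net.uk",
        "com.au", "net.au", "org.au", "edu.au", "gov.au",
        "co.jp", "ne.jp", "or.jp", "ac.jp", "go.jp",
        "co.in", "net.in", "org.in", "gov.in",
        "com.br", "org.br", "gov.br", "net.br",
        "co.nz", "org.nz", "net.nz", "govt.nz",
        "com.mx", "org.mx", "gob.mx",
        "co.za", "org.za", "gov.za",
        "com.cn", "org.cn", "gov.cn", "net.cn",
        "com.sg", "com.hk", "com.tw", "com.ar", "com.co", "com.tr",
        "co.kr", "or.kr", "go.kr", "co.il", "org.il", "gov.il",
    }
)


@dataclass(frozen=True)
class NormalizedLink:
    """Registered domain plus a kind tag: 'domain', 'twitter', 'shortener'."""

    domain: str | None
    kind: str  # 'domain' | 'twitter' | 'shortener' | 'invalid'


def normalize_domain(
    url: str, shorteners: frozenset[str] | set[str] = DEFAULT_SHORTENERS
) -> NormalizedLink:
    """Lowercased registered domain of a URL-like string.

    ``www.foxnews.com`` hosts normalize to ``foxnews.com``.  Links to
    twitter.com and to known URL shorteners are tagged so callers can
    exclude them and count them separately.  Unparseable input yields
    ``NormalizedLink(None, 'invalid')``.
    """
    if not url or not isinstance(url, str):
        return NormalizedLink(None, "invalid")
    s = url.strip()
    if "://" not in s:
        s = "//" + s.lstrip("/")
    try:
        host = urlsplit(s).hostname
    except ValueError:
        return NormalizedLink(None, "invalid")
    if not host or "." not in host:
        return NormalizedLink(None, "invalid")
    host = host.lower().rstrip(".")
    labels = host.split(".")
    if any(not lab for lab in labels):
        return NormalizedLink(None, "invalid")
    if len(labels) >= 3 and ".".join(labels[-2:]) in _MULTI_SUFFIXES:
        dom = ".".join(labels[-3:])
    else:
        dom = ".".join(labels[-2:])
    if dom in ("twitter.com", "x.com"):
        return NormalizedLink(dom, "twitter")
    if dom in shorteners or host in shorteners:
        return NormalizedLink(dom, "shortener")
    return NormalizedLink(dom, "domain")


@dataclass
class LinkAccounting:
    """Conservation report: all = twitter + shortened + retained."""

    all_links: int = 0
    twitter_links: int = 0
    shortened_links: int = 0
    retained_links: int = 0
    invalid_links: int = 0  # subset of retained with no parseable domain
    distinct_domains: int = 0
    qualifying_domains: int = 0

    def check(self) -> bool:
        return self.all_links == self.twitter_links + self.shortened_links + self.retained_links


def build_domain_matrix(
    tweets: Iterable[TweetRecord],
    membership: Mapping[str, Hashable],
    min_total: int = 10,
    per_community: bool = False,
    shorteners: frozenset[str] | set[str] = DEFAULT_SHORTENERS,
) -> tuple[pd.DataFrame, LinkAccounting]:
    """Community x domain link-fraction matrix plus link accounting.

    Links from accounts without a community assignment are ignored.  Twitter
    links and shortener links are excluded and counted separately; the
    remaining ("retained") links are tallied per (community, domain).
    Columns keep domains whose total share count across all communities is
    at least ``min_total`` (or, with ``per_community=True``, domains shared
    at least ``min_total`` times by some single community).  Rows are
    renormalized over the qualifying columns so each nonempty row sums to 1;
    a community with no qualifying links gets an all-zero row.
    """
    counts: dict[Hashable, dict[str, int]] = {}
    acct = LinkAccounting()
    communities = sorted(set(membership.values()), key=str)
    for c in communities:
        counts[c] = {}
    for t in tweets:
        c = membership.get(t.account_id)
        if c is None:
            continue
        for url in t.urls:
            acct.all_links += 1
            link = normalize_domain(url, shorteners)
            if link.kind == "twitter":
                acct.twitter_links += 1
            elif link.kind == "shortener":
                acct.shortened_links += 1
            else:
                acct.retained_links += 1
                if link.kind == "invalid":
                    acct.invalid_links += 1
                else:
                    counts[c][link.domain] = counts[c].get(link.domain, 0) + 1

    totals: dict[str, int] = {}
    per_comm_max: dict[str, int] = {}
    for c, d in counts.items():
        for dom, n in d.items():
            totals[dom] = totals.get(dom, 0) + n
            per_comm_max[dom] = max(per_comm_max.get(dom, 0), n)
    acct.distinct_domains = len(totals)
    source = per_comm_max if per_community else totals
    keep = sorted(dom for dom, n in source.items() if n >= min_total)
    acct.qualifying_domains = len(keep)

    mat = pd.DataFrame(0.0, index=pd.Index(communities, name="community"),
                       columns=pd.Index(keep, name="domain"))
    for c in communities:
        row = np.array([counts[c].get(dom, 0) for dom in keep], dtype=float)
        s = row.sum()
        if s > 0:
            mat.loc[c] = row / s
        else:
            warnings.warn(f"community {c!r} has no qualifying links", stacklevel=2)
    return mat, acct


# ---------------------------------------------------------------------------
# first-component scoring


class LinkedDomainPCA(TransformerMixin, BaseEstimator):
    """First principal component of the domain frequency matrix.

    Columns are mean-centered (no variance scaling: the rows are
    compositions, and scaling would inflate rare domains); the first right
    singular vector gives per-domain loadings and the projections give
    per-community scores.  Orientation: the loading of ``anchor_domain``
    (if given and present) is forced positive, otherwise the
    largest-magnitude loading is forced positive.

    Attributes
    ----------
    loadings_ : pandas Series, domain -> loading.
    scores_ : pandas Series, community -> first-component score (zero mean).
    mean_ : column means used for centering.
    degenerate_ : True when the centered matrix is rank 0 (all rows equal).
    """

    def __init__(self, anchor_domain: str | None = None):
        self.anchor_domain = anchor_domain

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need at least 2 communities and 2 domains")
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = X.values.mean(axis=0)
        centered = X.values - self.mean_
        self.degenerate_ = not np.any(np.abs(centered) > 1e-12)
        if self.degenerate_:
            warnings.warn("all communities identical; scores degenerate to 0", stacklevel=2)
            v = np.zeros(X.shape[1])
            v[0] = 1.0
            scores = np.zeros(X.shape[0])
        else:
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            v = vt[0]
            if self.anchor_domain is not None and self.anchor_domain in X.columns:
                j = list(X.columns).index(self.anchor_domain)
                ref = v[j]
            else:
                ref = v[np.argmax(np.abs(v))]
            if ref < 0:
                v = -v
            scores = centered @ v
        self.loadings_ = pd.Series(v, index=X.columns, name="loading")
        self.scores_ = pd.Series(scores, index=X.index, name="linked_domain_score")
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        vals = X.reindex(columns=self.feature_names_in_, fill_value=0.0).values
        return (vals - self.mean_) @ self.loadings_.values


@dataclass
class DomainScore:
    """Community scores and domain loadings on the first component."""

    scores: pd.Series
    loadings: pd.Series
    degenerate: bool = False


def pca_first_component(
    matrix: pd.DataFrame, anchor_domain: str | None = None
) -> DomainScore:
    est = LinkedDomainPCA(anchor_domain=anchor_domain).fit(matrix)
    return DomainScore(est.scores_, est.loadings_, est.degenerate_)


# ---------------------------------------------------------------------------
# clustering of 1-D scores


@dataclass
class ClusterAssignment:
    """Community -> cluster labels with the dendrogram and silhouette trace."""

    labels: dict[Hashable, int]
    dendrogram: np.ndarray
    chosen_k: int
    silhouette: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False

    def members(self) -> dict[int, list[Hashable]]:
        out: dict[int, list[Hashable]] = {}
        for c, lab in self.labels.items():
            out.setdefault(lab, []).append(c)
        return out


class DomainScoreClustering(BaseEstimator):
    """Hierarchical clustering of 1-D linked-domain scores.

    Centroid linkage by default (average linkage optional); every cut from
    2 to ``max_k`` clusters is scored by silhouette and the best cut is
    kept unless ``force_k`` overrides it.  On 1-D data both linkages give
    clusters contiguous in score order.
    """

    def __init__(self, max_k: int = 6, method: str = "centroid",
                 force_k: int | None = None):
        self.max_k = max_k
        self.method = method
        self.force_k = force_k

    def fit(self, X, y=None):
        scores = np.asarray(X, dtype=float).reshape(-1, 1)
        n = scores.shape[0]
        if n < 3:
            raise ValueError("need at least 3 communities to cluster")
        if self.method not in ("centroid", "average"):
            raise ValueError("method must be 'centroid' or 'average'")
        self.linkage_ = linkage(scores, method=self.method)
        self.silhouette_by_k_ = {}
        degenerate = np.allclose(scores, scores[0])
        if degenerate:
            warnings.warn("all scores equal; single trivial cluster", stacklevel=2)
            self.labels_ = np.zeros(n, dtype=int)
            self.chosen_k_ = 1
            self.silhouette_ = float("nan")
            self.degenerate_ = True
            return self
        self.degenerate_ = False
        labels_by_k = {}
        for k in range(2, min(self.max_k, n - 1) + 1):
            lab = fcluster(self.linkage_, k, criterion="maxclust") - 1
            if len(np.unique(lab)) < 2 or len(np.unique(lab)) >= n:
                warnings.warn(f"cut k={k} degenerate; skipped", stacklevel=2)
                continue
            labels_by_k[k] = lab
            self.silhouette_by_k_[k] = float(silhouette_score(scores, lab))
        if not self.silhouette_by_k_:
            self.labels_ = np.zeros(n, dtype=int)
            self.chosen_k_ = 1
            self.silhouette_ = float("nan")
            return self
        best_k = max(self.silhouette_by_k_, key=lambda k: (self.silhouette_by_k_[k], -k))
        k = self.force_k if self.force_k is not None else best_k
        if k not in labels_by_k:
            raise ValueError(f"forced cut k={k} unavailable")
        self.best_k_ = best_k
        self.chosen_k_ = k
        self.labels_ = labels_by_k[k]
        self.silhouette_ = self.silhouette_by_k_[k]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_scores(
    scores: DomainScore | pd.Series,
    max_k: int = 6,
    method: str = "centroid",
    force_k: int | None = None,
) -> ClusterAssignment:
    s = scores.scores if isinstance(scores, DomainScore) else scores
    est = DomainScoreClustering(max_k=max_k, method=method, force_k=force_k).fit(s.values)
    return ClusterAssignment(
        labels={c: int(l) for c, l in zip(s.index, est.labels_)},
        dendrogram=est.linkage_,
        chosen_k=est.chosen_k_,
        silhouette=est.silhouette_,
        silhouette_by_k=dict(est.silhouette_by_k_),
        degenerate=est.degenerate_,
    )


# ---------------------------------------------------------------------------
# media-bias join

POLITICAL_ORDINAL = {
    "Left": 1, "Center Left": 2, "Center": 3, "Center Right": 4, "Right": 5,
}


def read_bias_table(path) -> dict[str, str]:
    """CSV ``domain,category`` -> dict."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            if len(row) >= 2:
                out[row[0].strip().lower()] = row[1].strip()
    return out


def join_bias_categories(
    loadings: DomainScore | pd.Series, bias_table: Mapping[str, str]
) -> dict:
    """Group domain loadings by media-bias category.

    Returns per-category loading arrays, the match rate (fraction of matrix
    domains present in the table), and the Pearson correlation between
    loading and the 1..5 Left->Right ordinal over politically categorized
    domains (NaN when fewer than 2 such domains or zero variance).
    """
    l = loadings.loadings if isinstance(loadings, DomainScore) else loadings
    per_cat: dict[str, list[float]] = {}
    ordinal_pairs: list[tuple[float, int]] = []
    matched = 0
    for dom, load in l.items():
        cat = bias_table.get(str(dom).lower())
        if cat is None:
            continue
        matched += 1
        per_cat.setdefault(cat, []).append(float(load))
        if cat in POLITICAL_ORDINAL:
            ordinal_pairs.append((float(load), POLITICAL_ORDINAL[cat]))
    if len(ordinal_pairs) >= 2:
        x = np.array([p[0] for p in ordinal_pairs])
        y = np.array([p[1] for p in ordinal_pairs], dtype=float)
        if x.std() > 0 and y.std() > 0:
            corr = float(np.corrcoef(x, y)[0, 1])
        else:
            corr = float("nan")
    else:
        corr = float("nan")
    return {
        "per_category": {c: np.array(v) for c, v in sorted(per_cat.items())},
        "ordinal_correlation": corr,
        "match_rate": matched / len(l) if len(l) else float("nan"),
        "n_matched": matched,
    }
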