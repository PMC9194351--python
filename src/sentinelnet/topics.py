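"""Keyword topic filters, tweet-rate normalization, sampling, and tables.

Topic membership is plain lowercase substring containment — "mask" matches
"masks" and also "unmasked".  That bluntness is deliberate (it is how the
surveillance keywords are defined); a word-boundary mode is available via
``word_boundary=True``.  Topics nest: a child topic matches only within its
parent's matches, e.g. the misinformation subtopics apply only to tweets
that already pass the COVID gate.
"""

from __future__ import annotations

import csv
import re
import warnings
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2_contingency

from .corpus import TweetRecord

__all__ = [
    "KeywordTopicSpec",
    "TopicRegistry",
    "default_topics",
    "match_topic",
    "matches_topic",
    "per_capita_rates",
    "daily_per_15_active",
    "stratified_sample",
    "chi_square",
    "reconstruct_counts",
    "read_contingency_table",
]


@dataclass(frozen=True)
class KeywordTopicSpec:
    """A named list of lowercase substrings, optionally nested in a parent."""

    name: str
    substrings: tuple[str, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        if not self.substrings:
            raise ValueError(f"topic {self.name!r} has no substrings")
        object.__setattr__(
            self, "substrings", tuple(s.lower() for s in self.substrings)
        )


class TopicRegistry:
    """Resolves topic names and parent chains (cycles rejected)."""

    def __init__(self, specs: Iterable[KeywordTopicSpec] = ()):
        self._specs: dict[str, KeywordTopicSpec] = {}
        for s in specs:
            self.add(s)

    def add(self, spec: KeywordTopicSpec) -> None:
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> KeywordTopicSpec:
        if name not in self._specs:
            raise KeyError(f"undefined topic {name!r}")
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def names(self) -> list[str]:
        return sorted(self._specs)

    def chain(self, name: str) -> list[KeywordTopicSpec]:
        """Spec plus ancestors, child first; raises on cycles/undefined parents."""
        out, seen = [], set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise ValueError(f"topic parent cycle at {cur!r}")
            seen.add(cur)
            spec = self[cur]
            out.append(spec)
            cur = spec.parent
        return out


def _text_matches(text_lower: str, spec: KeywordTopicSpec, word_boundary: bool) -> bool:
    if word_boundary:
        return any(
            re.search(r"\b" + re.escape(s) + r"\b", text_lower) for s in spec.substrings
        )
    return any(s in text_lower for s in spec.substrings)


def matches_topic(
    text: str, name: str, registry: TopicRegistry, word_boundary: bool = False
) -> bool:
    low = text.lower()
    return all(
        _text_matches(low, spec, word_boundary) for spec in registry.chain(name)
    )


def match_topic(
    tweets: Iterable[TweetRecord],
    name: str,
    registry: TopicRegistry,
    word_boundary: bool = False,
) -> list[TweetRecord]:
    """Tweets containing a topic substring and matching the parent chain."""
    registry.chain(name)  # validate up front
    return [t for t in tweets if matches_topic(t.text, name, registry, word_boundary)]


def default_topics() -> TopicRegistry:
    """Registry shipped with the package.

    The lists live as editable text files under ``data/keywords/`` with a
    YAML manifest declaring parent relationships; the code treats them
    purely as data.
    """
    pkg = resources.files("sentinelnet") / "data" / "keywords"
    manifest = yaml.safe_load((pkg / "topics.yaml").read_text(encoding="utf-8"))
    reg = TopicRegistry()
    for name, info in manifest.items():
        lines = (pkg / info["file"]).read_text(encoding="utf-8").splitlines()
        subs = tuple(s.strip() for s in lines if s.strip() and not s.startswith("#"))
        reg.add(KeywordTopicSpec(name=name, substrings=subs, parent=info.get("parent")))
    return reg


# ---------------------------------------------------------------------------
# tweet rates


def per_capita_rates(
    counts: Mapping[Hashable, int], aads: Mapping[Hashable, int]
) -> pd.DataFrame:
    """Per-capita and scaled per-capita topical tweet rates by community.

    rate_i = topical tweets / active account days; scaled_i = rate_i divided
    by the sum of rates over communities, so scaled rates sum to 1 when any
    tweeting occurred (all-zero rates are flagged with a warning and left 0).
    """
    comms = sorted(counts, key=str)
    rows = []
    for c in comms:
        aad = aads[c]
        if aad <= 0:
            raise ValueError(f"community {c!r} has nonpositive active account days")
        rows.append((c, counts[c], aad, counts[c] / aad))
    df = pd.DataFrame(rows, columns=["community", "count", "active_account_days", "rate"])
    df = df.set_index("community")
    total = df["rate"].sum()
    if total > 0:
        df["scaled_rate"] = df["rate"] / total
    else:
        warnings.warn("all rates zero; scaled rates undefined", stacklevel=2)
        df["scaled_rate"] = 0.0
    return df


def daily_per_15_active(
    daily_counts: Mapping, daily_active: Mapping
) -> pd.Series:
    """Display normalization: daily tweets per 15 active accounts."""
    days = sorted(daily_counts)
    vals = []
    for d in days:
        act = daily_active.get(d, 0)
        vals.append(daily_counts[d] / act * 15 if act > 0 else np.nan)
    return pd.Series(vals, index=pd.Index(days, name="day"), name="per_15_active")


# ---------------------------------------------------------------------------
# stratified sampling scaffold for human coding


def _equal_quota_allocation(avail: dict[Hashable, int], n: int) -> dict[Hashable, int]:
    """Equal shares with largest-remainder rounding, capped at availability.

    Communities that cannot fill their quota are fixed at availability and
    the remainder is re-allocated among the rest until stable.
    """
    alloc = {c: 0 for c in avail}
    free = dict(avail)
    remaining = n
    while remaining > 0 and free:
        share = remaining / len(free)
        base = {c: int(share) for c in free}
        rem = remaining - sum(base.values())
        order = sorted(free, key=lambda c: (-(share - base[c]), str(c)))
        for c in order[:rem]:
            base[c] += 1
        capped = {c for c in free if base[c] >= free[c]}
        if not capped:
            for c in free:
                alloc[c] += base[c]
            break
        for c in capped:
            alloc[c] += free[c]
            remaining -= free[c]
        for c in capped:
            del free[c]
    return alloc


def stratified_sample(
    tweets_by_stratum: Mapping[Hashable, Sequence[TweetRecord]],
    community_of: Mapping[str, Hashable],
    n_per_stratum: int = 100,
    seed: int = 0,
    balance_by_community: bool = True,
) -> dict[Hashable, list[TweetRecord]]:
    """Random sample of up to n tweets per (cluster, topic) stratum.

    Strata with fewer than n tweets are taken whole.  With community
    balancing, each community in the stratum receives an equal quota
    (largest-remainder rounding); quotas exceeding a community's tweet count
    are redistributed among the others.  Deterministic for a given seed.
    """
    out: dict[Hashable, list[TweetRecord]] = {}
    for key in sorted(tweets_by_stratum, key=str):
        pool = list(tweets_by_stratum[key])
        rng = np.random.default_rng((seed, zlib.crc32(str(key).encode("utf-8"))))
        if not pool:
            warnings.warn(f"stratum {key!r} is empty", stacklevel=2)
            out[key] = []
            continue
        if len(pool) <= n_per_stratum:
            out[key] = sorted(pool, key=lambda t: t.tweet_id)
            continue
        if not balance_by_community:
            idx = rng.choice(len(pool), size=n_per_stratum, replace=False)
            out[key] = [pool[i] for i in sorted(idx)]
            continue
        by_comm: dict[Hashable, list[TweetRecord]] = {}
        for t in sorted(pool, key=lambda t: t.tweet_id):
            by_comm.setdefault(community_of.get(t.account_id, "__none__"), []).append(t)
        avail = {c: len(v) for c, v in by_comm.items()}
        alloc = _equal_quota_allocation(avail, n_per_stratum)
        sample: list[TweetRecord] = []
        for c in sorted(by_comm, key=str):
            take = alloc[c]
            lst = by_comm[c]
            if take >= len(lst):
                sample.extend(lst)
            else:
                idx = rng.choice(len(lst), size=take, replace=False)
                sample.extend(lst[i] for i in sorted(idx))
        out[key] = sample
    return out


# ---------------------------------------------------------------------------
# contingency tables


def chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column sum")
    stat, p, df, _ = chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def reconstruct_counts(
    n_per_row: Mapping[Hashable, int], percent_positive: Mapping[Hashable, float]
) -> pd.DataFrame:
    """Rebuild a rows x {positive, negative} count table from printed N and %.

    Percentages are converted to counts by rounding to the nearest integer
    per cell.
    """
    rows = list(n_per_row)
    pos = [round(n_per_row[r] * percent_positive[r] / 100.0) for r in rows]
    neg = [n_per_row[r] - p for r, p in zip(rows, pos)]
    return pd.DataFrame(
        {"positive": pos, "negative": neg}, index=pd.Index(rows, name="row")
    )


def read_contingency_table(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0][1:]
    idx, data = [], []
    for row in rows[1:]:
        idx.append(row[0])
        data.append([int(x) for x in row[1:]])
    return pd.DataFrame(data, index=pd.Index(idx, name="row"), columns=header)
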