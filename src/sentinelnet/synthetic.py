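"""Synthetic tweet-stream generator with planted structure.

Generates a corpus exhibiting the statistical features the surveillance
pipeline assumes: assortative retweeting within communities (probability
``p_in`` that a retweet stays inside the retweeter's community, targets
drawn by preferential attachment on in-degree so in-degrees are heavy
tailed), community-specific domain-sharing preferences (a configurable
distribution over a domain pool per community, letting tests plant opposing
media "poles"), daily tweet text assembled from a community-permuted
Zipf-like vocabulary (so baseline cross-community trigram overlap is near
zero) with topic keywords emitted at community-specific rates, and planted
cross-cluster virality events: a verbatim text injected into chosen
communities on a known day.

The generator is deterministic for a given seed, and returns the ground
truth (community labels, domain assignments, event records) alongside the
tweets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np

from .corpus import ObservationWindow, TweetRecord

__all__ = ["PlantedEvent", "SyntheticConfig", "generate_corpus", "write_truth"]


@dataclass(frozen=True)
class PlantedEvent:
    """A verbatim text injected into given communities on a given day."""

    day: int  # 0-based day offset within the window
    text: str
    communities: tuple[int, ...]
    copies_per_community: int = 10


@dataclass
class SyntheticConfig:
    """Study conditions for the generated corpus.

    Defaults: 4 communities of 25 accounts, strongly assortative retweeting
    (p_in = 0.95), 42 days of content at 2 tweets per account-day, 3000
    retweet records, a 12-domain pool split into two preference poles, and a
    COVID gate token in 90% of tweets so documents are non-trivial.
    """

    n_communities: int = 4
    accounts_per_community: int = 25
    days: int = 42
    p_in: float = 0.95
    n_retweets: int = 3000
    tweets_per_account_day: float = 2.0
    start_day: date = date(2020, 7, 1)
    vocab_size: int = 2000
    tweet_length: tuple[int, int] = (8, 14)
    covid_rate: float = 0.9
    # cross-community "story of the day": every community inserts the day's
    # shared phrase into a fixed number of tweets, cycling through a weekly
    # news-volume pattern.  This yields the near-zero — but not identically
    # zero — baseline inter-cluster similarity regime with bounded
    # day-to-day fluctuation; without it the burst baseline is degenerate.
    shared_phrase_weekly: tuple[int, ...] = (6, 6, 6, 6, 5, 3, 3)
    n_shared_phrases: int = 15
    shared_phrase_length: int = 4
    link_rate: float = 0.25
    twitter_link_rate: float = 0.05
    shortener_link_rate: float = 0.02
    domain_pool: tuple[str, ...] = (
        "redeagle.com", "crimsonpost.com", "scarletwire.com",
        "rightledger.com", "patriotbeacon.com", "libertybugle.com",
        "bluebird.com", "azureherald.com", "cobaltdaily.com",
        "leftlantern.com", "progressgazette.com", "unionclarion.com",
    )
    # community -> distribution over domain_pool; default: first half of
    # communities prefer the first half of the pool, second half the rest
    domain_prefs: Mapping[int, Sequence[float]] | None = None
    # community -> {topic keyword: per-tweet emission probability}
    topic_rates: Mapping[int, Mapping[str, float]] | None = None
    events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 1 or self.accounts_per_community < 1:
            raise ValueError("need at least one community and one account")
        if not 0.0 <= self.p_in <= 1.0:
            raise ValueError("p_in must be in [0, 1]")
        if self.topic_rates is not None:
            for rates in self.topic_rates.values():
                if any(r < 0 for r in rates.values()):
                    raise ValueError("topic rates must be >= 0")
        for ev in self.events:
            if not 0 <= ev.day < self.days:
                raise ValueError(f"event day {ev.day} outside the window")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(
            self.start_day, self.start_day + timedelta(days=self.days - 1)
        )

    def default_domain_prefs(self) -> dict[int, np.ndarray]:
        if self.domain_prefs is not None:
            return {c: np.asarray(p, dtype=float) for c, p in self.domain_prefs.items()}
        npool = len(self.domain_pool)
        half = npool // 2
        out = {}
        for c in range(self.n_communities):
            p = np.zeros(npool)
            if c < self.n_communities / 2:
                p[:half] = 1.0
            else:
                p[half:] = 1.0
            out[c] = p / p.sum()
        return out


def _account_id(comm: int, i: int) -> str:
    return f"c{comm:02d}a{i:03d}"


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[TweetRecord], dict]:
    """Generate (tweets, truth) for the configured conditions.

    Truth records the community of every account, each community's domain
    preference vector, and the injected event tweet ids per community/day.
    """
    rng = np.random.default_rng(config.seed)
    ncomm, napc = config.n_communities, config.accounts_per_community
    accounts = {
        c: [_account_id(c, i) for i in range(napc)] for c in range(ncomm)
    }
    community_of = {a: c for c, lst in accounts.items() for a in lst}
    prefs = config.default_domain_prefs()
    # community-specific permutation of a shared Zipf vocabulary
    base_ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    zipf_p = (1.0 / base_ranks) / np.sum(1.0 / base_ranks)
    perms = {c: rng.permutation(config.vocab_size) for c in range(ncomm)}
    shared_phrases = [
        [f"s{k:02d}x{j}" for j in range(config.shared_phrase_length)]
        for k in range(config.n_shared_phrases)
    ]

    tweets: list[TweetRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"t{counter:08d}"

    def ts(day_offset: int) -> datetime:
        sec = int(rng.integers(0, 86400))
        return datetime.combine(
            config.start_day + timedelta(days=day_offset),
            datetime.min.time(),
            tzinfo=timezone.utc,
        ) + timedelta(seconds=sec)

    # --- retweet records (day 0): assortative with preferential attachment
    indeg = {c: np.ones(napc) for c in range(ncomm)}  # +1 smoothing
    for _ in range(config.n_retweets):
        c_src = int(rng.integers(ncomm))
        i_src = int(rng.integers(napc))
        src = accounts[c_src][i_src]
        if ncomm == 1 or rng.random() < config.p_in:
            c_tgt = c_src
        else:
            others = [c for c in range(ncomm) if c != c_src]
            c_tgt = int(others[int(rng.integers(len(others)))])
        p = indeg[c_tgt].copy()
        if c_tgt == c_src:
            p[i_src] = 0.0  # no self-retweet
        p = p / p.sum()
        i_tgt = int(rng.choice(napc, p=p))
        tgt = accounts[c_tgt][i_tgt]
        indeg[c_tgt][i_tgt] += 1.0
        tweets.append(
            TweetRecord(
                tweet_id=next_id(),
                account_id=src,
                timestamp=ts(0),
                text="rt placeholder",
                retweeted_account_id=tgt,
            )
        )

    # --- daily content tweets
    lo, hi = config.tweet_length
    topic_rates = config.topic_rates or {}
    event_ids: list[dict] = []
    for day in range(config.days):
        day_phrase = (
            shared_phrases[day % len(shared_phrases)] if shared_phrases else None
        )
        m_shared = (
            config.shared_phrase_weekly[day % len(config.shared_phrase_weekly)]
            if config.shared_phrase_weekly and day_phrase
            else 0
        )
        for c in range(ncomm):
            n_tweets = rng.poisson(config.tweets_per_account_day * napc)
            authors = rng.integers(0, napc, size=n_tweets)
            phrase_slots = (
                set(rng.choice(n_tweets, size=min(m_shared, n_tweets), replace=False).tolist())
                if m_shared and n_tweets
                else set()
            )
            for slot, i_author in enumerate(authors):
                length = int(rng.integers(lo, hi + 1))
                words = perms[c][rng.choice(config.vocab_size, size=length, p=zipf_p)]
                toks = [f"w{w:04d}" for w in words]
                if rng.random() < config.covid_rate:
                    toks.insert(int(rng.integers(len(toks) + 1)), "covid")
                if slot in phrase_slots:
                    toks.extend(day_phrase)
                for kw, rate in sorted(topic_rates.get(c, {}).items()):
                    if rng.random() < rate:
                        toks.append(kw)
                urls: list[str] = []
                r = rng.random()
                if r < config.twitter_link_rate:
                    urls.append(f"https://twitter.com/u/status/{int(rng.integers(10**9))}")
                elif r < config.twitter_link_rate + config.shortener_link_rate:
                    urls.append(f"https://bit.ly/{int(rng.integers(10**6))}")
                elif r < config.twitter_link_rate + config.shortener_link_rate + config.link_rate:
                    dom = config.domain_pool[int(rng.choice(len(config.domain_pool), p=prefs[c]))]
                    urls.append(f"https://www.{dom}/p/{int(rng.integers(10**6))}")
                tweets.append(
                    TweetRecord(
                        tweet_id=next_id(),
                        account_id=accounts[c][int(i_author)],
                        timestamp=ts(day),
                        text=" ".join(toks),
                        urls=tuple(urls),
                    )
                )
        for ev in config.events:
            if ev.day != day:
                continue
            for c in ev.communities:
                for _ in range(ev.copies_per_community):
                    tid = next_id()
                    author = accounts[c][int(rng.integers(napc))]
                    tweets.append(
                        TweetRecord(
                            tweet_id=tid,
                            account_id=author,
                            timestamp=ts(day),
                            text=ev.text,
                        )
                    )
                    event_ids.append(
                        {"tweet_id": tid, "community": c, "day": day, "account": author}
                    )

    tweets.sort(key=lambda t: (t.timestamp, t.tweet_id))
    truth = {
        "community_of": community_of,
        "domain_prefs": {c: prefs[c].tolist() for c in prefs},
        "domain_pool": list(config.domain_pool),
        "events": event_ids,
        "window": (config.window.start_day.isoformat(), config.window.end_day.isoformat()),
    }
    return tweets, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=str)
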