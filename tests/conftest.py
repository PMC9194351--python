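from datetime import date, datetime, timezone

import networkx as nx
import pytest

from sentinelnet.corpus import ObservationWindow, TweetRecord


def make_tweet(tid, account, day, text="hello", rt=None, urls=(), month=7, hour=12):
    return TweetRecord(
        tweet_id=str(tid),
        account_id=str(account),
        timestamp=datetime(2020, month, day, hour, 0, tzinfo=timezone.utc),
        text=text,
        retweeted_account_id=rt,
        urls=tuple(urls),
    )


@pytest.fixture
def window():
    return ObservationWindow(date(2020, 7, 1), date(2020, 7, 30))


@pytest.fixture
def two_cycles():
    """Two disjoint reciprocal dyads; optimal split is {a,b} | {c,d} with Q=0.5."""
    g = nx.DiGraph()
    for u, v in [("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")]:
        g.add_edge(u, v, weight=1)
    return g
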