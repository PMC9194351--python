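"""Tweet corpus data model, JSONL readers/writers, and activity accounting.

The corpus is a flat sequence of :class:`TweetRecord` objects, read from a
line-delimited JSON stream.  Activity accounting implements the attrition
convention used for sentinel monitoring: an account is *active* on a day if
it tweets on that day **or any later day** of the observation window, so the
number of active account days equals the span from the window start through
the account's last observed tweet.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "ObservationWindow",
    "CodingMatrix",
    "read_tweet_stream",
    "write_tweet_stream",
    "tweets_by_account",
    "last_tweet_day",
    "active_on_day",
    "active_account_days",
    "daily_active_accounts",
    "read_coding_matrix",
    "krippendorff_alpha",
]


@dataclass(frozen=True)
class TweetRecord:
    """One post.

    ``retweeted_account_id``, when present, identifies the ORIGINAL poster of
    the retweeted content.  A self-retweet (equal to ``account_id``) is a
    valid record but contributes no edge to the retweet network.
    """

    tweet_id: str
    account_id: str
    timestamp: datetime
    text: str
    retweeted_account_id: str | None = None
    urls: tuple[str, ...] = ()

    @property
    def is_retweet(self) -> bool:
        return self.retweeted_account_id is not None

    def to_json(self) -> str:
        d = {
            "tweet_id": self.tweet_id,
            "account_id": self.account_id,
            "timestamp": self.timestamp.isoformat(),
            "text": self.text,
            "retweeted_account_id": self.retweeted_account_id,
            "urls": list(self.urls),
        }
        return json.dumps(d, ensure_ascii=False)


@dataclass(frozen=True)
class ObservationWindow:
    """Calendar window with a fixed day-bucketing timezone.

    Every daily bucketing in the pipeline goes through :meth:`day_of` so a
    single timezone rule applies throughout.  Default is UTC; reproducing
    analyses demarcated in US Eastern time requires
    ``day_boundary_tz="America/New_York"``.
    """

    start_day: date
    end_day: date
    day_boundary_tz: str = "UTC"

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must be <= end_day")

    @property
    def tzinfo(self) -> timezone | ZoneInfo:
        if self.day_boundary_tz.upper() == "UTC":
            return timezone.utc
        return ZoneInfo(self.day_boundary_tz)

    def day_of(self, ts: datetime) -> date:
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        return ts.astimezone(self.tzinfo).date()

    def contains(self, ts: datetime) -> bool:
        return self.start_day <= self.day_of(ts) <= self.end_day

    def days(self) -> list[date]:
        n = (self.end_day - self.start_day).days + 1
        return [self.start_day + timedelta(days=i) for i in range(n)]

    @property
    def n_days(self) -> int:
        return (self.end_day - self.start_day).days + 1


def _parse_record(obj: Mapping) -> TweetRecord:
    ts = obj["timestamp"]
    if isinstance(ts, (int, float)):
        ts = datetime.fromtimestamp(float(ts), tz=timezone.utc)
    else:
        ts = datetime.fromisoformat(str(ts))
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
    rid = obj.get("retweeted_account_id")
    return TweetRecord(
        tweet_id=str(obj["tweet_id"]),
        account_id=str(obj["account_id"]),
        timestamp=ts,
        text=str(obj.get("text", "")),
        retweeted_account_id=None if rid in (None, "") else str(rid),
        urls=tuple(obj.get("urls") or ()),
    )


def read_tweet_stream(
    path: str | Path,
    window: ObservationWindow | None = None,
    on_malformed: str = "skip",
) -> Iterator[TweetRecord]:
    """Yield tweet records from a JSONL file, in file order.

    Records with timestamps outside ``window`` are dropped.  Malformed lines
    (bad JSON, or missing tweet_id / account_id / timestamp) are skipped with
    a warning when ``on_malformed='skip'``, or raise when ``'error'``.
    """
    if on_malformed not in ("skip", "error"):
        raise ValueError("on_malformed must be 'skip' or 'error'")
    path = Path(path)
    n_skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = _parse_record(json.loads(line))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                if on_malformed == "error":
                    raise ValueError(f"malformed record at line {lineno}: {exc}") from exc
                n_skipped += 1
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)
                continue
            if window is not None and not window.contains(rec.timestamp):
                continue
            yield rec
    if n_skipped:
        logger.warning("skipped %d malformed line(s) in %s", n_skipped, path)


def write_tweet_stream(records: Iterable[TweetRecord], path: str | Path) -> int:
    """Write records as UTF-8 JSONL; returns the number written."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# activity accounting


def tweets_by_account(tweets: Iterable[TweetRecord]) -> dict[str, list[TweetRecord]]:
    out: dict[str, list[TweetRecord]] = {}
    for t in tweets:
        out.setdefault(t.account_id, []).append(t)
    return out


def last_tweet_day(
    tweets: Iterable[TweetRecord], window: ObservationWindow
) -> dict[str, date]:
    """Last in-window tweet day per account."""
    out: dict[str, date] = {}
    for t in tweets:
        if not window.contains(t.timestamp):
            continue
        d = window.day_of(t.timestamp)
        prev = out.get(t.account_id)
        if prev is None or d > prev:
            out[t.account_id] = d
    return out


def active_on_day(
    tweets: Sequence[TweetRecord],
    account: str,
    day: date,
    window: ObservationWindow,
) -> bool:
    """True iff ``account`` tweets on ``day`` or any later day inside the window."""
    if not (window.start_day <= day <= window.end_day):
        return False
    last = last_tweet_day(tweets, window).get(account)
    return last is not None and last >= day


def active_account_days(
    tweets: Sequence[TweetRecord],
    account: str,
    window: ObservationWindow,
) -> int:
    """Number of window days the account is active.

    Equals ``last_tweet_day - window.start_day + 1`` for an account with at
    least one in-window tweet, and 0 otherwise.
    """
    last = last_tweet_day(tweets, window).get(account)
    if last is None:
        return 0
    return (last - window.start_day).days + 1


def daily_active_accounts(
    tweets: Sequence[TweetRecord],
    accounts: Iterable[str],
    window: ObservationWindow,
) -> dict[date, int]:
    """Count, per window day, how many of ``accounts`` are active on that day."""
    lasts = last_tweet_day(tweets, window)
    accounts = list(accounts)
    out: dict[date, int] = {}
    for day in window.days():
        out[day] = sum(1 for a in accounts if a in lasts and lasts[a] >= day)
    return out


# ---------------------------------------------------------------------------
# inter-coder reliability


@dataclass
class CodingMatrix:
    """Units x coders nominal codes; ``None`` marks a missing code."""

    units: list[str]
    coders: list[str]
    values: list[list[object | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.coders) < 2:
            raise ValueError("need at least 2 coders")
        if any(len(row) != len(self.coders) for row in self.values):
            raise ValueError("each row must have one entry per coder")
        if not any(sum(v is not None for v in row) >= 2 for row in self.values):
            raise ValueError("need at least one unit with >= 2 non-missing codes")


def read_coding_matrix(path: str | Path) -> CodingMatrix:
    """Read a CSV with a unit-id column followed by one column per coder."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    coders = header[1:]
    units, values = [], []
    for row in rows[1:]:
        units.append(row[0])
        values.append([cell if cell != "" else None for cell in row[1:]])
    return CodingMatrix(units=units, coders=coders, values=values)


def krippendorff_alpha(matrix: CodingMatrix) -> float:
    """Krippendorff's alpha for nominal data, coincidence-matrix formulation.

    Units with fewer than two non-missing codes are dropped.  Each pairable
    unit *u* with m_u codes contributes 1/(m_u - 1) per ordered code pair to
    the coincidence matrix; alpha = 1 - D_o / D_e with observed disagreement
    D_o the off-diagonal coincidence mass and expected disagreement from the
    value marginals.  If every recorded code is identical, disagreement is
    undefined and 1.0 is returned with a warning (perfect-agreement
    convention).
    """
    cats: list[object] = []
    cat_index: dict[object, int] = {}
    rows = []
    for row in matrix.values:
        vals = [v for v in row if v is not None]
        if len(vals) < 2:
            continue
        for v in vals:
            if v not in cat_index:
                cat_index[v] = len(cats)
                cats.append(v)
        rows.append(vals)
    if not rows:
        raise ValueError("no unit has >= 2 non-missing codes")
    k = len(cats)
    if k == 1:
        warnings.warn(
            "all observed codes identical; alpha undefined, returning 1.0",
            stacklevel=2,
        )
        return 1.0
    coin = np.zeros((k, k))
    for vals in rows:
        m = len(vals)
        idx = [cat_index[v] for v in vals]
        for i, a in enumerate(idx):
            for j, b in enumerate(idx):
                if i != j:
                    coin[a, b] += 1.0 / (m - 1)
    n_total = coin.sum()
    marg = coin.sum(axis=1)
    d_o = n_total - np.trace(coin)
    d_e = (n_total**2 - np.sum(marg**2)) / (n_total - 1)
    if d_e == 0:
        warnings.warn("zero expected disagreement; returning 1.0", stacklevel=2)
        return 1.0
    return float(1.0 - d_o / d_e)
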