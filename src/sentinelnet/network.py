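"""Retweet network, directed modularity, Louvain communities, sentinels.

The retweet network is a weighted directed graph: an edge u -> v with weight
w records that account u retweeted account v (the original poster) w times.
The weighted in-degree of a node is therefore the number of times it was
retweeted, and the weighted out-degree the number of times it retweeted
others.

Community detection maximizes the directed, weighted modularity

    Q = (1/w) sum_ij (A_ij - win_i * wout_j / w) delta(C_i, C_j)

where A_ij counts retweets of i by j, w is total edge weight and win/wout
the weighted in/out degrees.  The greedy multilevel (Louvain-type) optimizer
operates on the symmetrized modularity matrix (B + B^T)/2, the standard
GenLouvain treatment of directed modularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .corpus import TweetRecord

__all__ = [
    "build_retweet_network",
    "largest_connected_component",
    "modularity",
    "LouvainCommunities",
    "louvain_partition",
    "SentinelSet",
    "select_sentinels",
    "sentinel_indegree_coverage",
    "rand_and_zrand",
    "write_edgelist",
    "read_edgelist",
    "write_partition",
    "read_partition",
]


def build_retweet_network(tweets: Iterable[TweetRecord]) -> nx.DiGraph:
    """Build the weighted retweet graph from a tweet stream.

    Non-retweets are ignored; self-retweets are excluded and add no node.
    Edge direction: retweeter -> original poster.
    """
    g = nx.DiGraph()
    for t in tweets:
        if t.retweeted_account_id is None:
            continue
        if t.retweeted_account_id == t.account_id:
            continue
        u, v = t.account_id, t.retweeted_account_id
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g


def largest_connected_component(net: nx.DiGraph) -> nx.DiGraph:
    """Induced subgraph on the largest weakly connected component.

    Retweet graphs are near-acyclic, so connectivity is read in the weak
    sense: a retweet in either direction links two accounts.  Size ties are
    broken by the lexicographically smallest sorted node-id tuple.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no connected component")
    comps = [sorted(c) for c in nx.weakly_connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c))
    return net.subgraph(comps[0]).copy()


def _degree_arrays(net: nx.DiGraph, nodes: Sequence[Hashable]):
    win = np.array([net.in_degree(n, weight="weight") for n in nodes], dtype=float)
    wout = np.array([net.out_degree(n, weight="weight") for n in nodes], dtype=float)
    return win, wout


def modularity(
    net: nx.DiGraph,
    partition: Mapping[Hashable, int],
    resolution: float = 1.0,
) -> float:
    """Directed, weighted modularity of a node -> community assignment.

    The null-model term includes the diagonal i = j contributions even
    though the graph has no self-loops.
    """
    nodes = list(net.nodes())
    missing = [n for n in nodes if n not in partition]
    if missing:
        raise ValueError(f"partition missing {len(missing)} node(s), e.g. {missing[0]!r}")
    w = net.size(weight="weight")
    if w <= 0:
        raise ValueError("network has no edge weight")
    win, wout = _degree_arrays(net, nodes)
    labels = np.array([partition[n] for n in nodes])
    within = 0.0
    for u, v, d in net.edges(data="weight"):
        if partition[u] == partition[v]:
            within += d
    null = 0.0
    for c in np.unique(labels):
        mask = labels == c
        null += win[mask].sum() * wout[mask].sum()
    return within / w - resolution * null / (w * w)


def _modularity_matrix(net: nx.DiGraph, nodes: Sequence[Hashable], resolution: float):
    """Symmetrized modularity matrix (B + B^T)/2 with B_ij = A_ij - g*win_i*wout_j/w."""
    # adjacency with A[i, j] = weight of retweets of i by j (edge j -> i)
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight").T
    win, wout = _degree_arrays(net, nodes)
    w = a.sum()
    b = a - resolution * np.outer(win, wout) / w
    return (b + b.T) / 2.0, w


def _greedy_move_pass(b: np.ndarray, labels: np.ndarray, order: np.ndarray, tol: float) -> bool:
    """One sweep of local node moves on the (symmetric) quality matrix."""
    improved = False
    n = b.shape[0]
    ncomm = labels.max() + 1
    for i in order:
        row = b[i]
        gains = np.zeros(ncomm)
        np.add.at(gains, labels, row)
        cur = labels[i]
        gains[cur] -= row[i]  # self term is community-invariant
        best = int(np.argmax(gains))
        if gains[best] > gains[cur] + tol:
            labels[i] = best
            improved = True
    return improved


def _aggregate(b: np.ndarray, labels: np.ndarray):
    comms, inv = np.unique(labels, return_inverse=True)
    k = len(comms)
    s = np.zeros((b.shape[0], k))
    s[np.arange(b.shape[0]), inv] = 1.0
    return s.T @ b @ s, inv


class LouvainCommunities(ClusterMixin, BaseEstimator):
    """Greedy multilevel modularity maximization on the symmetrized matrix.

    Parameters
    ----------
    resolution : float, default=1.0
        Resolution parameter multiplying the null-model term.
    n_restarts : int, default=5
        Independent restarts with shuffled node orders; best modularity kept.
    random_state : int, default=0
        Seeds the node-visitation shuffles; a given seed is bit-reproducible.
    tol : float, default=1e-10
        Minimum quality gain for a node move.

    Attributes
    ----------
    labels_ : ndarray of dense community labels aligned with ``nodes_``.
    partition_ : dict node -> community label.
    modularity_ : directed modularity of the returned partition.
    """

    def __init__(
        self,
        resolution: float = 1.0,
        n_restarts: int = 5,
        random_state: int = 0,
        tol: float = 1e-10,
    ):
        self.resolution = resolution
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.tol = tol

    def fit(self, X: nx.DiGraph, y=None):
        net = X
        nodes = sorted(net.nodes())
        if net.size(weight="weight") <= 0:
            raise ValueError("network has no edge weight")
        bsym, w = _modularity_matrix(net, nodes, self.resolution)
        best_labels, best_q = None, -np.inf
        for restart in range(self.n_restarts):
            rng = np.random.default_rng((self.random_state, restart))
            labels = self._one_run(bsym, rng)
            q = self._quality(bsym, labels) / w
            if q > best_q + self.tol:
                best_q, best_labels = q, labels
        # dense relabeling in order of first appearance
        _, dense = np.unique(best_labels, return_inverse=True)
        self.nodes_ = nodes
        self.labels_ = dense
        self.partition_ = {n: int(c) for n, c in zip(nodes, dense)}
        self.modularity_ = modularity(net, self.partition_, self.resolution)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @staticmethod
    def _quality(b: np.ndarray, labels: np.ndarray) -> float:
        q = 0.0
        for c in np.unique(labels):
            mask = labels == c
            q += b[np.ix_(mask, mask)].sum()
        return q

    def _one_run(self, bsym: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = bsym.shape[0]
        node_map = np.arange(n)  # original node -> current supernode
        b = bsym
        while True:
            m = b.shape[0]
            labels = np.arange(m)
            order = rng.permutation(m)
            while _greedy_move_pass(b, labels, order, self.tol):
                order = rng.permutation(m)
            if len(np.unique(labels)) == m:
                break
            b, inv = _aggregate(b, labels)
            node_map = inv[node_map]
            if b.shape[0] == m:
                break
        return node_map


def louvain_partition(
    net: nx.DiGraph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 5,
) -> dict[Hashable, int]:
    """Functional wrapper over :class:`LouvainCommunities`; returns node -> label."""
    est = LouvainCommunities(
        resolution=resolution, n_restarts=n_restarts, random_state=seed
    )
    return est.fit(net).partition_


# ---------------------------------------------------------------------------
# sentinel selection


@dataclass
class SentinelSet:
    """Per-community sentinel lists ordered by weighted in-degree (desc)."""

    per_community: dict[int, list[tuple[Hashable, float]]] = field(default_factory=dict)

    def accounts(self, community: int | None = None) -> list[Hashable]:
        if community is not None:
            return [a for a, _ in self.per_community.get(community, [])]
        return [a for lst in self.per_community.values() for a, _ in lst]


def select_sentinels(
    net: nx.DiGraph,
    partition: Mapping[Hashable, int],
    k: int = 15,
    min_size: int = 1,
    community_filter: Callable[[int, list[Hashable]], bool] | None = None,
) -> SentinelSet:
    """Top-k most-retweeted accounts per community.

    Communities smaller than ``min_size`` are dropped; ``community_filter``
    (community label, member list) -> bool is an injectable screen standing
    in for language / locality filtering, default pass-through.  In-degree
    ties break toward the lexicographically smaller account id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members: dict[int, list[Hashable]] = {}
    for n, c in partition.items():
        members.setdefault(c, []).append(n)
    out = SentinelSet()
    for c, nodes in sorted(members.items()):
        if len(nodes) < min_size:
            continue
        if community_filter is not None and not community_filter(c, nodes):
            continue
        ranked = sorted(
            ((n, float(net.in_degree(n, weight="weight"))) for n in nodes),
            key=lambda t: (-t[1], str(t[0])),
        )
        out.per_community[c] = ranked[:k]
    return out


def sentinel_indegree_coverage(
    net: nx.DiGraph,
    partition: Mapping[Hashable, int],
    k: int = 15,
) -> tuple[dict[int, float], dict[str, float]]:
    """Fraction of each community's total in-degree captured by its top-k nodes.

    Returns (per-community coverage, summary with mean/median/IQR).  A
    community whose nodes were never retweeted has undefined coverage and is
    reported as NaN and excluded from the summary.
    """
    members: dict[int, list[Hashable]] = {}
    for n, c in partition.items():
        members.setdefault(c, []).append(n)
    cov: dict[int, float] = {}
    for c, nodes in sorted(members.items()):
        indeg = sorted(
            (float(net.in_degree(n, weight="weight")) for n in nodes), reverse=True
        )
        total = sum(indeg)
        cov[c] = float("nan") if total == 0 else sum(indeg[:k]) / total
    vals = np.array([v for v in cov.values() if np.isfinite(v)])
    if len(vals):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary = {
            "mean": float(vals.mean()),
            "median": float(med),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
        }
    else:
        summary = {"mean": float("nan"), "median": float("nan"),
                   "iqr_low": float("nan"), "iqr_high": float("nan")}
    return cov, summary


# ---------------------------------------------------------------------------
# partition comparison


def _pair_counts(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    return int(sum(comb(int(c), 2) for c in counts))


def rand_and_zrand(
    p1: Mapping[Hashable, int], p2: Mapping[Hashable, int]
) -> tuple[float, float]:
    """Rand index and z-Rand score between two partitions.

    Both partitions are restricted to their common node set.  The Rand index
    is the fraction of node pairs classified consistently.  The z-Rand score
    standardizes w12, the number of pairs co-assigned in both partitions,
    by its exact mean and variance under the permutation null that fixes
    both partitions' group sizes (hypergeometric model).  Degenerate nulls
    (zero variance) yield z = NaN.
    """
    common = sorted(set(p1) & set(p2))
    n = len(common)
    if n < 2:
        raise ValueError("need >= 2 common nodes")
    l1 = np.array([p1[x] for x in common])
    l2 = np.array([p2[x] for x in common])
    m = comb(n, 2)
    m1 = _pair_counts(l1)
    m2 = _pair_counts(l2)
    # contingency-based count of pairs together in both
    _, inv1 = np.unique(l1, return_inverse=True)
    _, inv2 = np.unique(l2, return_inverse=True)
    cont = np.zeros((inv1.max() + 1, inv2.max() + 1), dtype=np.int64)
    np.add.at(cont, (inv1, inv2), 1)
    w12 = int(sum(comb(int(c), 2) for c in cont.ravel() if c >= 2))
    rand = (m - m1 - m2 + 2 * w12) / m

    mean = m1 * m2 / m

    def _c(labels: np.ndarray, mk: int) -> float:
        _, counts = np.unique(labels, return_counts=True)
        return (
            n * (n**2 - 3 * n - 2)
            - 8 * (n + 1) * mk
            + 4 * float(np.sum(counts.astype(float) ** 3))
        )

    c1, c2 = _c(l1, m1), _c(l2, m2)
    var = (
        m / 16.0
        - (4 * m1 - 2 * m) ** 2 * (4 * m2 - 2 * m) ** 2 / (256.0 * m**2)
        + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
        + ((4 * m1 - 2 * m) ** 2 - 4 * c1 - 4 * m)
        * ((4 * m2 - 2 * m) ** 2 - 4 * c2 - 4 * m)
        / (64.0 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var <= 0 or not np.isfinite(var):
        warnings.warn("degenerate z-Rand null (zero variance)", stacklevel=2)
        return float(rand), float("nan")
    return float(rand), float((w12 - mean) / np.sqrt(var))


# ---------------------------------------------------------------------------
# flat-file interfaces


def write_edgelist(net: nx.DiGraph, path) -> None:
    """TSV ``source<TAB>retweeted_by<TAB>weight`` (source = original poster)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tretweeted_by\tweight\n")
        for u, v, d in sorted(net.edges(data="weight")):
            fh.write(f"{v}\t{u}\t{d}\n")


def read_edgelist(path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            src, rby, w = line.rstrip("\n").split("\t")
            g.add_edge(rby, src, weight=int(w))
    return g


def write_partition(partition: Mapping[Hashable, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("account_id,community\n")
        for n, c in sorted(partition.items(), key=lambda t: str(t[0])):
            fh.write(f"{n},{c}\n")


def read_partition(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            n, c = line.rstrip("\n").rsplit(",", 1)
            out[n] = int(c)
    return out
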