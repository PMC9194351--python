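"""End-to-end orchestration of the sentinel surveillance pipeline.

Stages: retweet network -> largest component -> Louvain communities ->
sentinel selection -> domain matrix -> linked-domain PCA -> score
clustering -> topic rates -> daily similarity series -> burst flags ->
LSA attribution.  Every artifact is written as plain text (CSV/TSV/JSON)
and the run manifest echoes all parameters and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burst as burst_mod
from . import corpus as corpus_mod
from . import domains as domains_mod
from . import network as network_mod
from . import topics as topics_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of a full run; defaults match the method's stated settings."""

    corpus_path: str = ""
    output_dir: str = "sentinelnet_run"
    start_day: str = ""
    end_day: str = ""
    timezone: str = "UTC"
    k_sentinels: int = 15
    min_community_size: int = 5
    domain_min_total: int = 10
    anchor_domain: str | None = None
    linkage: str = "centroid"
    max_clusters: int = 6
    force_clusters: int | None = None
    topics: tuple[str, ...] = ()
    gate_topic: str = "covid"
    burst_threshold: float = 2.0
    burn_in_days: int = 7
    lsa_components: int = 5
    match_threshold: float = 0.5
    resolution: float = 1.0
    seed: int = 0

    def manifest(self) -> dict:
        return dataclasses.asdict(self)


def _window(cfg: PipelineConfig, tweets) -> corpus_mod.ObservationWindow:
    if cfg.start_day and cfg.end_day:
        from datetime import date
        return corpus_mod.ObservationWindow(
            date.fromisoformat(cfg.start_day), date.fromisoformat(cfg.end_day),
            cfg.timezone,
        )
    days = [t.timestamp.date() for t in tweets]
    return corpus_mod.ObservationWindow(min(days), max(days), cfg.timezone)


def run_pipeline(cfg: PipelineConfig, tweets=None) -> dict:
    """Execute every stage and write artifacts; returns them in memory too.

    ``tweets`` may be passed directly (e.g. a generated corpus); otherwise
    the JSONL at ``cfg.corpus_path`` is read.  Deterministic for fixed
    seeds; artifact files are overwritten idempotently.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if tweets is None:
        tweets = list(corpus_mod.read_tweet_stream(cfg.corpus_path))
    else:
        tweets = list(tweets)
    window = _window(cfg, tweets)
    artifacts: dict = {"window": window}

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("network")
    net = network_mod.build_retweet_network(tweets)
    lcc = network_mod.largest_connected_component(net)
    network_mod.write_edgelist(lcc, out / "retweet_lcc.tsv")

    _stage("louvain")
    partition = network_mod.louvain_partition(
        lcc, seed=cfg.seed, resolution=cfg.resolution
    )
    network_mod.write_partition(partition, out / "communities.csv")
    artifacts["partition"] = partition
    artifacts["modularity"] = network_mod.modularity(lcc, partition, cfg.resolution)

    _stage("sentinels")
    sentinels = network_mod.select_sentinels(
        lcc, partition, k=cfg.k_sentinels, min_size=cfg.min_community_size
    )
    coverage, cov_summary = network_mod.sentinel_indegree_coverage(
        lcc, partition, cfg.k_sentinels
    )
    with (out / "sentinels.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "per_community": {
                    str(c): [[str(a), d] for a, d in lst]
                    for c, lst in sentinels.per_community.items()
                },
                "coverage": {str(c): v for c, v in coverage.items()},
                "coverage_summary": cov_summary,
            },
            fh, indent=1,
        )
    artifacts["sentinels"] = sentinels

    # sentinel accounts' community membership drives the content stages
    membership = {
        a: c for c, lst in sentinels.per_community.items() for a, _ in lst
    }
    artifacts["membership"] = membership

    _stage("domains")
    matrix, accounting = domains_mod.build_domain_matrix(
        tweets, membership, min_total=cfg.domain_min_total
    )
    matrix.to_csv(out / "domain_matrix.tsv", sep="\t")
    artifacts["domain_matrix"] = matrix
    artifacts["link_accounting"] = accounting
    if matrix.shape[0] >= 3 and matrix.shape[1] >= 2:
        score = domains_mod.pca_first_component(matrix, anchor_domain=cfg.anchor_domain)
        clusters = domains_mod.cluster_scores(
            score, max_k=cfg.max_clusters, method=cfg.linkage,
            force_k=cfg.force_clusters,
        )
        score.scores.to_csv(out / "domain_scores.csv")
        with (out / "clusters.json").open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    "labels": {str(c): l for c, l in clusters.labels.items()},
                    "chosen_k": clusters.chosen_k,
                    "silhouette": clusters.silhouette,
                    "silhouette_by_k": clusters.silhouette_by_k,
                },
                fh, indent=1,
            )
        artifacts["domain_score"] = score
        artifacts["clusters"] = clusters
        cluster_of = clusters.labels
    else:
        logger.warning("domain matrix too small for PCA/clustering; single cluster")
        cluster_of = {c: 0 for c in matrix.index}
        artifacts["clusters"] = None

    _stage("topics")
    registry = topics_mod.default_topics()
    aads = {
        c: sum(
            corpus_mod.active_account_days(tweets, a, window)
            for a, _ in sentinels.per_community.get(c, [])
        )
        for c in sentinels.per_community
    }
    rate_tables = {}
    for topic in cfg.topics or registry.names():
        if topic not in registry:
            raise ValueError(f"unknown topic {topic!r}")
        matched = topics_mod.match_topic(tweets, topic, registry)
        counts = {c: 0 for c in sentinels.per_community}
        for t in matched:
            c = membership.get(t.account_id)
            if c is not None:
                counts[c] += 1
        usable = {c: aads[c] for c in counts if aads[c] > 0}
        if usable:
            rate_tables[topic] = topics_mod.per_capita_rates(
                {c: counts[c] for c in usable}, usable
            )
    if rate_tables:
        pd.concat(rate_tables, names=["topic"]).to_csv(out / "topic_rates.csv")
    artifacts["rate_tables"] = rate_tables

    _stage("burst")
    documents = burst_mod.build_daily_documents(
        tweets, membership, window, registry, cfg.gate_topic
    )
    series = burst_mod.similarity_series(documents, cluster_of, window)
    burst_mod.write_similarity_series(series, out / "similarity.csv")
    flags = []
    stationarity = {}
    for pair, s in sorted(series.items(), key=lambda kv: str(kv[0])):
        if s.notna().sum() >= 10:
            stationarity[pair] = burst_mod.stationarity_check(s)
        for flag in burst_mod.flag_bursts(
            s, pair, cfg.burst_threshold, cfg.burn_in_days
        ):
            flag = burst_mod.attribute_burst(
                flag, documents, cluster_of, s,
                threshold=cfg.burst_threshold,
                match_threshold=cfg.match_threshold,
                n_components=cfg.lsa_components,
            )
            flags.append(flag)
    with (out / "flags.json").open("w", encoding="utf-8") as fh:
        json.dump(
            [
                {
                    "day": str(f.day),
                    "pair": [str(x) for x in f.pair],
                    "H": f.h,
                    "topical": {
                        str(cl): ids for cl, ids in
                        ((cl, sorted(d)) for cl, d in f.topical.items())
                    },
                    "removed": f.removed,
                    "recomputed_H": f.recomputed_h,
                    "attributed": f.attributed,
                }
                for f in flags
            ],
            fh, indent=1,
        )
    artifacts["series"] = series
    artifacts["flags"] = flags
    artifacts["stationarity"] = stationarity

    manifest = cfg.manifest()
    manifest["n_tweets"] = len(tweets)
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return artifacts
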