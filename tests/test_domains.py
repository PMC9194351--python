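import warnings

import numpy as np
import pandas as pd
import pytest

from sentinelnet.domains import (
    DomainScoreClustering,
    LinkedDomainPCA,
    build_domain_matrix,
    cluster_scores,
    join_bias_categories,
    normalize_domain,
    pca_first_component,
    read_bias_table,
)

from conftest import make_tweet


class TestNormalizeDomain:
    @pytest.mark.parametrize(
        "url,domain,kind",
        [
            ("https://www.foxnews.com/politics/x", "foxnews.com", "domain"),
            ("http://motherjones.com", "motherjones.com", "domain"),
            ("https://news.bbc.co.uk/story", "bbc.co.uk", "domain"),
            ("https://bit.ly/abc", "bit.ly", "shortener"),
            ("https://twitter.com/u/status/1", "twitter.com", "twitter"),
            ("www.example.com/path", "example.com", "domain"),
        ],
    )
    def test_normalization_and_tagging(self, url, domain, kind):
        link = normalize_domain(url)
        assert (link.domain, link.kind) == (domain, kind)

    @pytest.mark.parametrize("url", ["", "not a url", "http://", "::::"])
    def test_unparseable_yields_none(self, url):
        assert normalize_domain(url).domain is None


def tweets_with_links(spec):
    """spec: list of (account, [urls])"""
    return [
        make_tweet(i, acct, 2, urls=urls) for i, (acct, urls) in enumerate(spec)
    ]


class TestDomainMatrix:
    def test_threshold_and_renormalization(self):
        spec = [("a", [f"https://a.com/{i}" for i in range(12)] + ["https://b.com/1"] * 3)]
        tweets = tweets_with_links(spec)
        mat, acct = build_domain_matrix(tweets, {"a": 0}, min_total=10)
        assert list(mat.columns) == ["a.com"]
        assert mat.loc[0, "a.com"] == pytest.approx(1.0)
        assert acct.distinct_domains == 2
        assert acct.qualifying_domains == 1

    def test_two_communities_identity_pattern(self):
        spec = [
            ("a", ["https://left.com/x"] * 10),
            ("b", ["https://right.com/y"] * 10),
        ]
        mat, _ = build_domain_matrix(tweets_with_links(spec), {"a": 0, "b": 1})
        assert mat.shape == (2, 2)
        assert mat.loc[0, "left.com"] == 1.0
        assert mat.loc[1, "right.com"] == 1.0
        assert mat.loc[0, "right.com"] == 0.0

    def test_accounting_conservation(self):
        spec = [
            ("a", ["https://twitter.com/s/1", "https://bit.ly/x",
                   "https://a.com/1", "https://a.com/2", "bogus::::"]),
        ]
        _, acct = build_domain_matrix(tweets_with_links(spec), {"a": 0}, min_total=1)
        assert acct.all_links == 5
        assert acct.twitter_links == 1
        assert acct.shortened_links == 1
        assert acct.retained_links == 3  # includes the unparseable one
        assert acct.invalid_links == 1
        assert acct.check()

    def test_rows_stochastic_when_nonempty(self):
        rng = np.random.default_rng(2)
        spec = []
        for c in range(3):
            urls = [
                f"https://d{rng.integers(4)}.com/{i}" for i in range(40)
            ]
            spec.append((f"acct{c}", urls))
        mat, _ = build_domain_matrix(
            tweets_with_links(spec), {f"acct{c}": c for c in range(3)}, min_total=10
        )
        np.testing.assert_allclose(mat.sum(axis=1).values, 1.0, atol=1e-9)


class TestLinkedDomainPCA:
    def test_two_by_two_hand_eigendecomposition(self):
        mat = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["c1", "c2"],
                           columns=["a.com", "b.com"])
        score = pca_first_component(mat)
        # centered matrix [[.5,-.5],[-.5,.5]]; scores are +-1/sqrt(2)
        assert sorted(np.round(score.scores.values, 6)) == pytest.approx(
            [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_identical_rows_degenerate_to_zero(self):
        mat = pd.DataFrame([[0.5, 0.5]] * 3, index=list("abc"), columns=["x.com", "y.com"])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            score = pca_first_component(mat)
        assert np.allclose(score.scores.values, 0.0)
        assert score.degenerate

    def test_planted_poles_separate_with_correct_sign(self):
        rng = np.random.default_rng(0)
        rows, labels = [], []
        for c in range(6):
            pole = c < 3
            base = np.array([0.8, 0.2, 0.0, 0.0]) if pole else np.array([0.0, 0.0, 0.3, 0.7])
            noise = rng.dirichlet(np.ones(4)) * 0.05
            row = base + noise
            rows.append(row / row.sum())
            labels.append(pole)
        mat = pd.DataFrame(rows, index=[f"c{c}" for c in range(6)],
                           columns=["l1.com", "l2.com", "r1.com", "r2.com"])
        score = pca_first_component(mat, anchor_domain="r2.com")
        right = score.scores[[not l for l in labels]]
        left = score.scores[labels]
        assert (right > 0).all() and (left < 0).all()

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=4),
            index=list("abcd"), columns=[f"d{i}.com" for i in range(5)],
        )
        s1 = pca_first_component(mat, anchor_domain="d0.com").scores
        shuffled = mat.iloc[[2, 0, 3, 1], [4, 2, 0, 1, 3]]
        s2 = pca_first_component(shuffled, anchor_domain="d0.com").scores
        for c in mat.index:
            assert s2[c] == pytest.approx(s1[c])

    def test_transform_matches_fitted_scores(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.dirichlet(np.ones(4), size=5),
                           index=list("abcde"), columns=[f"d{i}.com" for i in range(4)])
        est = LinkedDomainPCA().fit(mat)
        np.testing.assert_allclose(est.transform(mat), est.scores_.values, atol=1e-12)

    def test_dominant_domain_removal_shifts_only_its_users(self):
        # two communities lean on dom.com, others never touch it
        mat = pd.DataFrame(
            [
                [0.6, 0.2, 0.2, 0.0],
                [0.5, 0.3, 0.2, 0.0],
                [0.0, 0.1, 0.1, 0.8],
                [0.0, 0.2, 0.1, 0.7],
            ],
            index=["u1", "u2", "v1", "v2"],
            columns=["dom.com", "x.com", "y.com", "z.com"],
        )
        full = pca_first_component(mat, anchor_domain="z.com").scores
        reduced_raw = mat.drop(columns=["dom.com"])
        reduced = reduced_raw.div(reduced_raw.sum(axis=1), axis=0)
        after = pca_first_component(reduced, anchor_domain="z.com").scores
        # non-users keep their ordering and side; users move
        assert (after[["v1", "v2"]] > 0).all() and (full[["v1", "v2"]] > 0).all()
        assert abs(after["u1"] - full["u1"]) > 1e-3


def _silhouette_oracle(scores, labels):
    scores = np.asarray(scores, dtype=float)
    vals = []
    for i, x in enumerate(scores):
        own = [abs(x - y) for j, y in enumerate(scores) if labels[j] == labels[i] and j != i]
        a = np.mean(own)
        b = min(
            np.mean([abs(x - y) for j, y in enumerate(scores) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestScoreClustering:
    def test_two_well_separated_pairs(self):
        scores = pd.Series([0.0, 0.1, 10.0, 10.1], index=list("abcd"))
        ca = cluster_scores(scores, max_k=3)
        assert ca.chosen_k == 2
        assert ca.labels["a"] == ca.labels["b"]
        assert ca.labels["c"] == ca.labels["d"]
        assert ca.labels["a"] != ca.labels["c"]
        expect = _silhouette_oracle(scores.values, [ca.labels[i] for i in scores.index])
        assert ca.silhouette == pytest.approx(expect)
        assert ca.silhouette > 0.98

    @pytest.mark.parametrize("method", ["centroid", "average"])
    def test_three_planted_triplets_recovered(self, method):
        scores = pd.Series(
            [0.0, 0.2, 0.4, 5.0, 5.2, 5.4, 11.0, 11.2, 11.4],
            index=[f"c{i}" for i in range(9)],
        )
        ca = cluster_scores(scores, max_k=5, method=method)
        assert ca.chosen_k == 3
        groups = ca.members()
        sets = sorted(tuple(sorted(v)) for v in groups.values())
        assert sets == [("c0", "c1", "c2"), ("c3", "c4", "c5"), ("c6", "c7", "c8")]

    def test_forced_cut_overrides_silhouette(self):
        scores = pd.Series([0.0, 0.1, 10.0, 10.1, 20.0, 20.1], index=list("abcdef"))
        ca = cluster_scores(scores, max_k=4, force_k=3)
        assert ca.chosen_k == 3
        assert max(ca.silhouette_by_k, key=ca.silhouette_by_k.get) in (2, 3)

    def test_all_equal_scores_degenerate(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            ca = cluster_scores(scores)
        assert ca.degenerate
        assert len(set(ca.labels.values())) == 1

    def test_one_dimensional_clusters_are_contiguous(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = np.sort(rng.normal(size=12))
            s = pd.Series(vals, index=[f"c{i}" for i in range(12)])
            ca = cluster_scores(s, max_k=4)
            labels = [ca.labels[f"c{i}"] for i in range(12)]
            # labels along the sorted line change value at most k-1 times
            changes = sum(1 for i in range(11) if labels[i] != labels[i + 1])
            assert changes == len(set(labels)) - 1


class TestBiasJoin:
    def test_two_point_perfect_correlation(self):
        loadings = pd.Series({"l.com": -1.0, "r.com": 1.0})
        out = join_bias_categories(loadings, {"l.com": "Left", "r.com": "Right"})
        assert out["ordinal_correlation"] == pytest.approx(1.0)
        assert out["match_rate"] == 1.0

    def test_independent_categories_near_zero(self):
        rng = np.random.default_rng(12)
        n = 10_000
        loadings = pd.Series(rng.normal(size=n), index=[f"d{i}.com" for i in range(n)])
        cats = ["Left", "Center Left", "Center", "Center Right", "Right"]
        table = {f"d{i}.com": cats[int(rng.integers(5))] for i in range(n)}
        out = join_bias_categories(loadings, table)
        assert abs(out["ordinal_correlation"]) < 0.05

    def test_unmatched_domains_reported(self):
        loadings = pd.Series({"a.com": 0.5, "b.com": -0.5})
        out = join_bias_categories(loadings, {"a.com": "Left"})
        assert out["match_rate"] == 0.5
        assert np.isnan(out["ordinal_correlation"])  # single point

    def test_read_bias_table(self, tmp_path):
        p = tmp_path / "bias.csv"
        p.write_text("domain,category\nFoo.com,Right\nbar.com,Pro Science\n")
        assert read_bias_table(p) == {"foo.com": "Right", "bar.com": "Pro Science"}
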