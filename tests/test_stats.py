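"""Statistics decision tree, post hoc tests, stars, and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dermaquant import (
    GroupSample,
    choose_route,
    cluster_groups,
    pairwise,
    run_comparison,
    stars,
)
from dermaquant.stats import dunn_test


def _normal_groups(rng, k=3, n=30, means=None, sds=None):
    means = means or [0.0] * k
    sds = sds or [1.0] * k
    return [
        GroupSample(f"g{i}", rng.normal(means[i], sds[i], size=n)) for i in range(k)
    ]


class TestChooseRoute:
    def test_normal_homoscedastic_goes_anova(self):
        rng = np.random.default_rng(0)
        route, shapiro_p, levene_p = choose_route(_normal_groups(rng))
        assert route == "anova+tukey"
        assert all(p >= 0.05 for p in shapiro_p.values()) and levene_p >= 0.05

    def test_nonnormal_group_routes_kruskal(self):
        """An exponential group makes Shapiro–Wilk reject at n=30."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = _normal_groups(rng, k=2) + [
                GroupSample("expo", rng.exponential(1.0, size=30))
            ]
            hits += choose_route(groups)[0] == "kruskal+dunn"
        assert hits >= 90

    def test_heteroscedastic_routes_welch(self):
        """SD 1 vs 5 makes Levene reject whenever normality is accepted."""
        routes = {"welch+games-howell": 0, "kruskal+dunn": 0, "anova+tukey": 0}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = _normal_groups(rng, k=2, sds=[1.0, 5.0])
            routes[choose_route(groups)[0]] += 1
        # Shapiro–Wilk false-rejects divert a few runs to the rank route,
        # but equal variances are never accepted.
        assert routes["anova+tukey"] == 0
        assert routes["welch+games-howell"] >= 80

    def test_small_group_rejected(self):
        groups = [GroupSample("a", [1.0, 2.0]), GroupSample("b", [1.0, 2.0, 3.0])]
        with pytest.raises(ValueError, match="n=2"):
            choose_route(groups)


class TestPairwise:
    def test_no_difference_limit(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=25)
        p, star = pairwise(GroupSample("a", values), GroupSample("b", values.copy()))
        assert p > 0.9 and star == "ns"

    def test_type_one_rate_near_alpha(self):
        rejections = 0
        for seed in range(400):
            rng = np.random.default_rng(seed)
            p, _ = pairwise(
                GroupSample("a", rng.normal(size=20)),
                GroupSample("b", rng.normal(size=20)),
            )
            rejections += p <= 0.05
        assert rejections / 400 == pytest.approx(0.05, abs=0.03)

    def test_power_against_large_shift(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            p, _ = pairwise(
                GroupSample("a", rng.normal(0, 1, 25)),
                GroupSample("b", rng.normal(2, 1, 25)),
            )
            hits += p <= 0.001
        assert hits >= 49


class TestOmnibus:
    def test_two_group_route_reduces_to_pairwise(self):
        rng = np.random.default_rng(9)
        a = GroupSample("a", rng.normal(size=15))
        b = GroupSample("b", rng.normal(0.5, 1, size=15))
        report = run_comparison([a, b])
        assert report.omnibus_p == pairwise(a, b)[0]
        assert len(report.pairwise) == 1

    def test_power_against_separated_groups(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            groups = _normal_groups(rng, k=3, n=20, means=[0, 0, 3])
            report = run_comparison(groups)
            row = report.pairwise.set_index(["group_a", "group_b"])
            hits += row.loc[("g0", "g2"), "p"] <= 0.001
        assert hits >= 28

    def test_route_recorded_consistently(self):
        rng = np.random.default_rng(17)
        groups = _normal_groups(rng, k=3, n=25)
        report = run_comparison(groups)
        normal = all(p >= report.alpha for p in report.shapiro_p.values())
        if not normal:
            assert report.route == "kruskal+dunn"
        elif report.levene_p < report.alpha:
            assert report.route == "welch+games-howell"
        else:
            assert report.route == "anova+tukey"


class TestDunn:
    def test_two_group_dunn_matches_kruskal(self):
        """For k=2 the Dunn z² equals the Kruskal–Wallis H, so the
        normal-tail p equals the chi²(1) p — an independent cross-check
        against scipy."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = GroupSample("a", rng.normal(size=12))
            b = GroupSample("b", rng.normal(0.8, 1, size=17))
            dunn_p = dunn_test([a, b])["p"].iloc[0]
            kw_p = sps.kruskal(a.values, b.values).pvalue
            assert dunn_p == pytest.approx(kw_p, rel=1e-10)

    def test_tie_correction_with_heavy_ties(self):
        a = GroupSample("a", [1, 1, 2, 2, 3, 3])
        b = GroupSample("b", [2, 2, 3, 3, 4, 4])
        dunn_p = dunn_test([a, b])["p"].iloc[0]
        kw_p = sps.kruskal(a.values, b.values).pvalue
        assert dunn_p == pytest.approx(kw_p, rel=1e-10)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.0005, "***"),
            (0.001, "***"),
            (0.01, "**"),
            (0.05, "*"),  # inclusive boundary
            (0.06, "ns"),
            (1.0, "ns"),
        ],
    )
    def test_caption_convention(self, p, label):
        assert stars(p) == label

    def test_monotone_in_p(self):
        order = {"***": 3, "**": 2, "*": 1, "ns": 0}
        ps = np.linspace(0, 1, 101)
        labels = [order[stars(p)] for p in ps]
        assert all(a >= b for a, b in zip(labels, labels[1:]))

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                stars(bad)


def _table(pairs):
    return pd.DataFrame(
        [{"group_a": a, "group_b": b, "p": p} for (a, b), p in pairs.items()]
    )


class TestClusters:
    def test_three_group_pattern(self):
        """ns within {5%,10%} and within {20%,40%}, all cross pairs
        significant → the three-cluster partition."""
        labels = ["control", "5%", "10%", "20%", "40%"]
        pairs = {
            pair: 0.001 for pair in itertools.combinations(labels, 2)
        }
        pairs[("5%", "10%")] = 0.8
        pairs[("20%", "40%")] = 0.6
        clusters = cluster_groups(_table(pairs), alpha=0.05)
        assert clusters == sorted(
            [frozenset({"control"}), frozenset({"5%", "10%"}),
             frozenset({"20%", "40%"})],
            key=lambda c: sorted(c),
        )

    def test_all_significant_gives_singletons(self):
        pairs = {p: 0.001 for p in itertools.combinations("abc", 2)}
        assert cluster_groups(_table(pairs)) == [
            frozenset("a"), frozenset("b"), frozenset("c")
        ]

    def test_none_significant_gives_one_cluster(self):
        pairs = {p: 0.9 for p in itertools.combinations("abc", 2)}
        assert cluster_groups(_table(pairs)) == [frozenset("abc")]

    def test_incomplete_table_rejected(self):
        pairs = {("a", "b"): 0.5}  # missing pairs with c
        table = _table(pairs)
        table.loc[len(table)] = ["a", "c", 0.5]
        with pytest.raises(ValueError, match="exactly once"):
            cluster_groups(table)

    def test_partition_property(self):
        """Clusters are disjoint and cover all groups, whatever the p's."""
        rng = np.random.default_rng(0)
        labels = list("abcdef")
        for _ in range(25):
            pairs = {p: rng.uniform() for p in itertools.combinations(labels, 2)}
            clusters = cluster_groups(_table(pairs))
            flat = [g for c in clusters for g in c]
            assert sorted(flat) == labels
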