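"""Group-comparison statistics for penetration read-outs.

The decision tree mirrors common practice for small-sample formulation
studies:

1. Shapiro–Wilk normality per group; Levene's test (mean-centred) for
   variance homogeneity.
2. All groups normal and variances homogeneous → one-way ANOVA with
   Tukey's HSD post hoc; normal but heteroscedastic → Welch ANOVA with
   Games–Howell; any group non-normal → Kruskal–Wallis with Dunn's
   post hoc (Holm-adjusted by default).
3. Two-sample comparisons use the independent t-test (Welch form under
   variance inhomogeneity) or the Mann–Whitney U test.

Significance labels follow the usual star convention
(* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001), and formulations are
clustered by connecting pairs that are *not* significantly different
and taking connected components.

Dunn's test is implemented here (rank z-statistics with tie correction)
because no post hoc library in the stack provides it; in the two-group
case its z² equals the Kruskal–Wallis H, which the tests exploit as an
independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "StatsReport",
    "choose_route",
    "run_comparison",
    "pairwise",
    "stars",
    "cluster_groups",
    "dunn_test",
]


@dataclass(frozen=True)
class GroupSample:
    """One group's measurements (ART, depth, or SCT)."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class StatsReport:
    """The test chain actually run, its p-values, and the group clusters."""

    route: str  # anova+tukey | welch+games-howell | kruskal+dunn
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p, star
    clusters: list[frozenset[str]]
    shapiro_p: dict[str, float] = field(default_factory=dict)
    levene_p: float | None = None
    alpha: float = 0.05


def _validate(groups: list[GroupSample]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g in groups:
        if g.n < 3:
            raise ValueError(f"group {g.group!r} has n={g.n} < 3; tests are undefined")
    labels = [g.group for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")


def choose_route(
    groups: list[GroupSample], alpha: float = 0.05
) -> tuple[str, dict[str, float], float]:
    """Pick the test route from normality and variance-homogeneity checks.

    Returns ``(route, shapiro_p_by_group, levene_p)``.  All groups
    normal (Shapiro–Wilk p ≥ alpha each) and Levene p ≥ alpha →
    ``anova+tukey``; normal but Levene rejects → ``welch+games-howell``;
    any group non-normal → ``kruskal+dunn``.
    """
    _validate(groups)
    shapiro_p = {g.group: float(sps.shapiro(g.values).pvalue) for g in groups}
    levene_p = float(
        sps.levene(*[g.values for g in groups], center="mean").pvalue
    )
    if any(p < alpha for p in shapiro_p.values()):
        route = "kruskal+dunn"
    elif levene_p < alpha:
        route = "welch+games-howell"
    else:
        route = "anova+tukey"
    return route, shapiro_p, levene_p


def dunn_test(groups: list[GroupSample]) -> pd.DataFrame:
    """Dunn's post hoc rank test (unadjusted two-sided p per pair).

    Pools all observations, ranks them (mid-ranks for ties), and for
    each pair computes ``z = (R̄_i − R̄_j) / σ_ij`` with
    ``σ_ij² = (N(N+1)/12 − T)(1/n_i + 1/n_j)`` where
    ``T = Σ(t³ − t) / (12(N − 1))`` corrects for ties.
    """
    values = np.concatenate([g.values for g in groups])
    n_total = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    start = 0
    for g in groups:
        mean_ranks[g.group] = float(ranks[start : start + g.n].mean())
        sizes[g.group] = g.n
        start += g.n

    rows = []
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    for a, b in itertools.combinations([g.group for g in groups], 2):
        sigma = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if sigma == 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / sigma
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "p": p})
    return pd.DataFrame(rows)


def _long_frame(groups: list[GroupSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.concatenate([g.values for g in groups]),
            "group": np.repeat([g.group for g in groups], [g.n for g in groups]),
        }
    )


def _posthoc(groups: list[GroupSample], route: str, p_adjust: str) -> pd.DataFrame:
    labels = [g.group for g in groups]
    if route == "anova+tukey":
        res = sps.tukey_hsd(*[g.values for g in groups])
        rows = [
            {"group_a": labels[i], "group_b": labels[j], "p": float(res.pvalue[i, j])}
            for i, j in itertools.combinations(range(len(groups)), 2)
        ]
        return pd.DataFrame(rows)
    if route == "welch+games-howell":
        gh = pg.pairwise_gameshowell(data=_long_frame(groups), dv="value", between="group")
        return pd.DataFrame(
            {"group_a": gh["A"], "group_b": gh["B"], "p": gh["pval"].astype(float)}
        )
    # kruskal+dunn
    table = dunn_test(groups)
    if p_adjust != "none":
        table["p"] = multipletests(table["p"].to_numpy(), method=p_adjust)[1]
    return table


def run_comparison(
    groups: list[GroupSample], alpha: float = 0.05, p_adjust: str = "holm"
) -> StatsReport:
    """Run the full decision tree: omnibus test, post hoc pairs, clusters.

    With exactly two groups the omnibus test *is* the pairwise test
    (t-test or Mann–Whitney per normality), so both report the same p.
    ``p_adjust`` applies to Dunn's raw p-values only ("holm",
    "bonferroni" or "none"); Tukey and Games–Howell are inherently
    multiplicity-adjusted.
    """
    route, shapiro_p, levene_p = choose_route(groups, alpha)

    if len(groups) == 2:
        p, star = pairwise(groups[0], groups[1], alpha)
        table = pd.DataFrame(
            [{"group_a": groups[0].group, "group_b": groups[1].group, "p": p, "star": star}]
        )
        clusters = cluster_groups(table, alpha)
        return StatsReport(route, p, table, clusters, shapiro_p, levene_p, alpha)

    arrays = [g.values for g in groups]
    if route == "anova+tukey":
        omnibus_p = float(sps.f_oneway(*arrays).pvalue)
    elif route == "welch+games-howell":
        welch = pg.welch_anova(data=_long_frame(groups), dv="value", between="group")
        p_col = "p_unc" if "p_unc" in welch.columns else "p-unc"
        omnibus_p = float(welch[p_col].iloc[0])
    else:
        omnibus_p = float(sps.kruskal(*arrays).pvalue)

    table = _posthoc(groups, route, p_adjust)
    table["star"] = [stars(p) for p in table["p"]]
    clusters = cluster_groups(table, alpha)
    return StatsReport(route, omnibus_p, table, clusters, shapiro_p, levene_p, alpha)


def pairwise(a: GroupSample, b: GroupSample, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sample comparison: t-test if both normal, else Mann–Whitney.

    Both groups normal by Shapiro–Wilk → independent t-test, in Welch
    form when Levene rejects variance homogeneity; otherwise the
    Mann–Whitney U test.  Returns ``(p, star)``.
    """
    _validate([a, b])
    normal = (
        sps.shapiro(a.values).pvalue >= alpha
        and sps.shapiro(b.values).pvalue >= alpha
    )
    if normal:
        equal_var = sps.levene(a.values, b.values, center="mean").pvalue >= alpha
        p = float(sps.ttest_ind(a.values, b.values, equal_var=equal_var).pvalue)
    else:
        p = float(
            sps.mannwhitneyu(a.values, b.values, alternative="two-sided").pvalue
        )
    return p, stars(p)


def stars(p: float) -> str:
    """Significance label: *** p ≤ 0.001, ** ≤ 0.01, * ≤ 0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def cluster_groups(pairwise_table: pd.DataFrame, alpha: float = 0.05) -> list[frozenset[str]]:
    """Partition groups into clusters of mutually indistinct members.

    Groups are vertices; an edge joins each pair with p > alpha (not
    significantly different); clusters are the connected components.
    The table must contain every unordered pair exactly once.
    """
    labels = sorted(
        set(pairwise_table["group_a"]).union(pairwise_table["group_b"])
    )
    expected = {frozenset(p) for p in itertools.combinations(labels, 2)}
    seen = [
        frozenset((a, b))
        for a, b in zip(pairwise_table["group_a"], pairwise_table["group_b"])
    ]
    if len(seen) != len(expected) or set(seen) != expected:
        raise ValueError(
            f"pairwise table must contain each of the {len(expected)} pairs exactly once"
        )
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    for (a, b), p in zip(seen, pairwise_table["p"]):
        if p > alpha:
            graph.add_edge(*sorted((a, b)))
    return sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c),
    )
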