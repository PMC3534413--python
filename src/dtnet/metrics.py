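"""Node metrics, summaries, components, label distances, group comparisons.

Conventions (chosen to match the network toolkits these analyses are run
with in practice):

* degree — number of incident edges in the simple graph (distinct partners);
* betweenness — unnormalised shortest-path betweenness, each unordered
  node pair counted once, tied shortest paths sharing credit fractionally;
* closeness — ``1 / sum of shortest-path distances`` to the nodes reachable
  from v (within its component).  Prose definitions often say "mean
  shortest distance", but the reciprocal-of-sum is what the classic igraph
  routine computes; ROC ranking is unaffected by the 1/(n-1) scale factor.
  Nodes with no reachable peer get closeness 0.

Betweenness and closeness are delegated to igraph's C implementations; the
test suite holds them against an explicit all-pairs shortest-path
enumeration oracle.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

from .graph import PiNetwork
from .records import LabelSet

__all__ = [
    "MetricMap",
    "MetricSummary",
    "ComponentReport",
    "DistanceProfile",
    "RankSumResult",
    "DegreeChangeReport",
    "compute_metric",
    "metric_summary",
    "component_report",
    "nearest_label_distance",
    "degree_change_report",
    "ranksum_compare",
    "EXACT_RANKSUM_MAX_N",
]

#: exact rank-sum enumeration is used up to this combined sample size
#: (tie-free samples only); beyond it the normal approximation with tie
#: correction takes over.
EXACT_RANKSUM_MAX_N = 12


@dataclass
class MetricMap:
    """A named node metric: protein ID -> non-negative value.

    ``values`` is the underlying dict; the common read-only mapping
    operations are forwarded for convenience.
    """

    name: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def keys(self):
        return self.values.keys()

    def items(self):
        return self.values.items()

    def get(self, key: str, default: Optional[float] = None) -> Optional[float]:
        return self.values.get(key, default)

    def restrict(self, keys: Iterable[str]) -> "MetricMap":
        keys = set(keys)
        return MetricMap(self.name, {k: v for k, v in self.values.items() if k in keys})


@dataclass
class MetricSummary:
    n: int
    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    max: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "max": self.max,
        }


@dataclass
class ComponentReport:
    """Connected components (size-descending) with per-label membership.

    ``disconnected`` counts labelled nodes outside the largest component
    (index 0).  Equal-size components order by their smallest node ID.
    """

    components: list[set[str]]
    label_counts: list[dict[str, int]]
    disconnected: dict[str, int]
    n_disconnected_proteins: int

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


@dataclass
class DistanceProfile:
    """Shortest-path distance from each source to the nearest target."""

    distances: dict[str, int]          # finite distances only
    unreachable: set[str]              # in network, no path to any target
    absent: set[str]                   # sources not present in the network

    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(self.distances.values()).items()))


@dataclass
class RankSumResult:
    p_value: float
    mean_a: float
    mean_b: float
    method: str  # "exact" or "normal"


@dataclass
class DegreeChangeReport:
    mean_change_a: float
    mean_change_b: float
    p_value: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# metric computation


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def compute_metric(network: PiNetwork, metric: str) -> MetricMap:
    """Compute degree, betweenness or closeness for every node."""
    if network.n_nodes == 0:
        raise ValueError("cannot compute metrics on an empty network")
    if metric == "degree":
        return MetricMap("degree", {v: float(d) for v, d in network.graph.degree()})
    g, nodes = _to_igraph(network.graph)
    if metric == "betweenness":
        vals = g.betweenness(directed=False)
    elif metric == "closeness":
        vals = g.closeness(mode="all", normalized=False)
        vals = [0.0 if (v is None or math.isnan(v)) else v for v in vals]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return MetricMap(metric, dict(zip(nodes, map(float, vals))))


def metric_summary(
    values: MetricMap | Mapping[str, float],
    restrict_to: Optional[Iterable[str]] = None,
) -> MetricSummary:
    """Moment summary of a metric vector, optionally over a protein subset.

    Skewness is g1 = m3/m2^1.5 and kurtosis the non-excess b2 = m4/m2^2
    (biased moment estimators, the convention of the classic ``moments``
    routines); both are NaN when the variance is zero.  The standard
    deviation uses the n-1 denominator.
    """
    data = dict(values.items()) if hasattr(values, "items") else dict(values)
    if restrict_to is not None:
        keys = set(restrict_to)
        data = {k: v for k, v in data.items() if k in keys}
    if not data:
        raise ValueError("no values left after restriction")
    x = np.asarray(sorted(data.values()), dtype=float)
    m2 = float(np.var(x))
    if m2 == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
    return MetricSummary(
        n=len(x),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        max=float(np.max(x)),
    )


# ---------------------------------------------------------------------------
# components and distances


def component_report(network: PiNetwork, labels: LabelSet) -> ComponentReport:
    components = sorted(
        (set(c) for c in nx.connected_components(network.graph)),
        key=lambda c: (-len(c), min(c)),
    )
    label_counts = [
        {name: len(comp & members) for name, members in labels.labels.items()}
        for comp in components
    ]
    giant = components[0] if components else set()
    nodes = network.nodes
    disconnected = {
        name: len((members & nodes) - giant) for name, members in labels.labels.items()
    }
    return ComponentReport(
        components=components,
        label_counts=label_counts,
        disconnected=disconnected,
        n_disconnected_proteins=len(nodes) - len(giant),
    )


def nearest_label_distance(
    network: PiNetwork, sources: Iterable[str], targets: Iterable[str]
) -> DistanceProfile:
    """Shortest-path distance from each source to the nearest target.

    Multi-source BFS from the target set; sources that are themselves
    targets get distance 0, sources with no path land in the unreachable
    bucket, and sources absent from the network are reported separately.
    """
    sources, targets = set(sources), set(targets)
    nodes = network.nodes
    present = sources & nodes
    absent = sources - nodes
    seeds = targets & nodes
    dist = (
        nx.multi_source_dijkstra_path_length(network.graph, seeds, weight=None)
        if seeds
        else {}
    )
    distances = {v: int(dist[v]) for v in present if v in dist}
    return DistanceProfile(
        distances=distances,
        unreachable=present - distances.keys(),
        absent=absent,
    )


# ---------------------------------------------------------------------------
# group comparisons


def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    combined = sorted(list(a) + list(b))
    rank = {v: i + 1 for i, v in enumerate(combined)}
    n, na = len(combined), len(a)
    w_obs = sum(rank[v] for v in a)
    mu = na * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in combinations(range(1, n + 1), na):
        total += 1
        if abs(sum(comb) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def ranksum_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Exact enumeration is used for tie-free samples with combined size
    <= EXACT_RANKSUM_MAX_N; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    a, b = list(map(float, values_a)), list(map(float, values_b))
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    combined = a + b
    tie_free = len(set(combined)) == len(combined)
    if len(set(combined)) == 1:
        # all values identical: no evidence of difference
        return RankSumResult(1.0, float(np.mean(a)), float(np.mean(b)), "degenerate")
    if tie_free and len(combined) <= EXACT_RANKSUM_MAX_N:
        p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "normal"
    return RankSumResult(min(p, 1.0), float(np.mean(a)), float(np.mean(b)), method)


def degree_change_report(
    full: MetricMap | Mapping[str, float],
    subset: MetricMap | Mapping[str, float],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> DegreeChangeReport:
    """Per-group mean degree change from the full network to a subset.

    change(v) = subset_degree(v) - full_degree(v); nodes missing from the
    subset count as degree 0 there, so changes are <= 0 under any filter.
    The two change vectors are compared with a two-sided rank-sum test.
    """
    full_d = dict(full.items()) if hasattr(full, "items") else dict(full)
    sub_d = dict(subset.items()) if hasattr(subset, "items") else dict(subset)
    if extra := set(sub_d) - set(full_d):
        raise ValueError(f"subset has nodes absent from full: {sorted(extra)[:5]}")
    changes = {v: sub_d.get(v, 0.0) - d for v, d in full_d.items()}
    ch_a = [changes[v] for v in set(group_a) & changes.keys()]
    ch_b = [changes[v] for v in set(group_b) & changes.keys()]
    if not ch_a or not ch_b:
        raise ValueError("a comparison group is empty after intersection")
    result = ranksum_compare(ch_a, ch_b)
    return DegreeChangeReport(
        mean_change_a=result.mean_a,
        mean_change_b=result.mean_b,
        p_value=result.p_value,
        n_a=len(ch_a),
        n_b=len(ch_b),
    )
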