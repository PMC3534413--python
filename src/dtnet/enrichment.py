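"""Rank-binned over-representation, ROC/AUC evaluation, pathway centrality.

Over-representation: proteins are ranked by a metric (degree, centrality),
grouped into bins of at least ``min_bin_size`` proteins without splitting
ties, and each bin is scored with the hypergeometric upper tail
P(X >= k) for k labelled proteins out of n drawn from a universe of N with
K labelled.  No multiple-testing correction is applied across bins (raw
p < alpha flags a bin); a correction can be layered on the exported
p-values if desired.

ROC: thresholds sweep the distinct score values in descending order, all
ties entering together, so the trapezoidal area under the curve equals the
tie-corrected Mann-Whitney statistic U/(P*N) exactly — the probability
that a random positive outranks a random negative, ties counted half.

Pathway centrality: the number of annotated pathways crossing a protein.
Whether proteins with no pathway annotation enter the universe (with value
0) or are dropped is an explicit switch; the two choices answer different
questions and can give very different AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .records import PathwayTable
from .metrics import MetricMap

__all__ = [
    "RankBin",
    "RankBins",
    "BinEnrichment",
    "RocCurve",
    "make_rank_bins",
    "hypergeom_upper_tail",
    "bin_overrepresentation",
    "roc_curve",
    "pathway_centrality_map",
]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k) of Hypergeom(N, K, n)."""
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


@dataclass
class RankBin:
    index: int                 # 1 = highest-metric bin
    members: set[str]
    high: float                # max metric value in the bin
    low: float                 # min metric value in the bin

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RankBins:
    bins: list[RankBin]
    metric_name: str
    min_bin_size: int

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for b in self.bins:
            out |= b.members
        return out


@dataclass
class BinEnrichmentRow:
    index: int
    size: int
    n_labeled: int
    high: float
    low: float
    p_value: float
    neg_log10_p: float
    significant: bool


@dataclass
class BinEnrichment:
    rows: list[BinEnrichmentRow]
    alpha: float
    universe_size: int
    n_labeled: int

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bin_index": r.index,
                    "metric_high": r.high,
                    "metric_low": r.low,
                    "bin_size": r.size,
                    "n_labeled": r.n_labeled,
                    "p_value": r.p_value,
                    "neg_log10_p": r.neg_log10_p,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


# ---------------------------------------------------------------------------


def make_rank_bins(
    values: MetricMap | Mapping[str, float], min_bin_size: int
) -> RankBins:
    """Greedy descending-rank binning that never splits a tied value.

    Each bin is filled to at least ``min_bin_size`` proteins, then extended
    to absorb every protein tied with its boundary value.  A leftover final
    bin smaller than ``min_bin_size`` merges into the previous bin.
    """
    name = values.name if isinstance(values, MetricMap) else "metric"
    data = dict(values.items())
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if min_bin_size > len(data):
        raise ValueError(
            f"min_bin_size {min_bin_size} exceeds universe size {len(data)}"
        )
    # distinct values descending, each with its tied protein group
    groups: dict[float, set[str]] = {}
    for node, val in data.items():
        groups.setdefault(float(val), set()).add(node)
    ordered = sorted(groups.items(), key=lambda kv: -kv[0])
    bins: list[RankBin] = []
    current: set[str] = set()
    high: Optional[float] = None
    low: Optional[float] = None
    for val, members in ordered:
        current |= members
        high = val if high is None else high
        low = val
        if len(current) >= min_bin_size:
            bins.append(RankBin(len(bins) + 1, current, high, low))
            current, high, low = set(), None, None
    if current:
        if len(current) >= min_bin_size or not bins:
            bins.append(RankBin(len(bins) + 1, current, high, low))
        else:
            last = bins[-1]
            bins[-1] = RankBin(last.index, last.members | current, last.high, low)
    return RankBins(bins=bins, metric_name=name, min_bin_size=min_bin_size)


def bin_overrepresentation(
    bins: RankBins, labeled: Iterable[str], alpha: float = 0.05
) -> BinEnrichment:
    """Hypergeometric upper-tail over-representation of a label per bin.

    p = P(X >= k), X ~ Hypergeom(N=universe, K=labelled in universe,
    n=bin size); a bin is flagged significant when p < alpha.
    """
    universe = bins.universe
    labeled = set(labeled) & universe
    if not labeled:
        raise ValueError("labelled set does not intersect the binned universe")
    N, K = len(universe), len(labeled)
    rows = []
    for b in bins:
        k = len(b.members & labeled)
        p = hypergeom_upper_tail(N, K, b.size, k)
        rows.append(
            BinEnrichmentRow(
                index=b.index,
                size=b.size,
                n_labeled=k,
                high=b.high,
                low=b.low,
                p_value=p,
                neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
                significant=p < alpha,
            )
        )
    return BinEnrichment(rows=rows, alpha=alpha, universe_size=N, n_labeled=K)


def roc_curve(
    scores: MetricMap | Mapping[str, float], positives: Iterable[str]
) -> RocCurve:
    """ROC of a node score as a binary-label predictor, AUC by trapezoid.

    One ROC vertex per distinct score value (ties enter together), points
    prefixed with (0, 0); FPR = FP/(FP+TN), TPR = TP/(TP+FN).  By this
    construction the trapezoidal AUC equals the tie-corrected Mann-Whitney
    U/(P*N).
    """
    data = dict(scores.items())
    pos = set(positives) & data.keys()
    n_pos = len(pos)
    n_neg = len(data) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    by_value: dict[float, tuple[int, int]] = {}
    for node, val in data.items():
        tp, fp = by_value.get(float(val), (0, 0))
        if node in pos:
            tp += 1
        else:
            fp += 1
        by_value[float(val)] = (tp, fp)
    fprs, tprs = [0.0], [0.0]
    tp = fp = 0
    for val in sorted(by_value, reverse=True):
        dtp, dfp = by_value[val]
        tp += dtp
        fp += dfp
        tprs.append(tp / n_pos)
        fprs.append(fp / n_neg)
    fpr = np.asarray(fprs)
    tpr = np.asarray(tprs)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def pathway_centrality_map(
    pathways: PathwayTable, universe: Iterable[str], include_zero: bool
) -> MetricMap:
    """Number of pathways crossing each protein of the universe.

    include_zero=True keys every universe protein (absent ones valued 0);
    include_zero=False restricts the map to proteins in >= 1 pathway.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    counts: dict[str, int] = {}
    for members in pathways.pathways.values():
        for p in members & universe:
            counts[p] = counts.get(p, 0) + 1
    if include_zero:
        values = {p: float(counts.get(p, 0)) for p in universe}
    else:
        values = {p: float(c) for p, c in counts.items()}
    return MetricMap("pathway_centrality", values)
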