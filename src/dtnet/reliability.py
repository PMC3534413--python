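"""Reliability sub-setting of an interactome.

Five criteria, each claimed in the literature to enrich for reliable
interactions, are supported:

* ``lpr<T``          — keep records from low-throughput publications.  The
  lpr of a publication is the number of distinct protein pairs it supports
  (after spoke-expanding its n-ary records); a record inherits its
  publication's count, and an edge supported by several publications takes
  the minimum.  Low lpr = a paper that reported few interactions.
* ``mi_intact>T`` / ``mi_psicquic>T`` — keep records whose externally
  supplied confidence score strictly exceeds the threshold.  A missing
  score fails the filter: an unscored record cannot certify reliability.
* ``no_predicted``   — drop computationally predicted (orthology-transferred)
  records.
* ``binary_only``    — keep only true binary (class B) records, removing
  n-ary data and its spoke-represented shadow.

All inequalities are strict.  lpr is computed on the full interactome
before any sub-setting, so that filtering cannot change a publication's
throughput class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

from .graph import RecordClass, expand_record_edges
from .records import Interactome, ValidationError

__all__ = [
    "FilterCriterion",
    "LprMap",
    "compute_lpr",
    "apply_filter",
    "apply_filters",
    "parse_filter_spec",
    "subset_overlap_counts",
]

_SCORE_KINDS = {"lpr_below", "mi_intact_above", "mi_psicquic_above"}
_KINDS = _SCORE_KINDS | {"exclude_predicted", "binary_only"}


@dataclass(frozen=True)
class FilterCriterion:
    """One reliability criterion; threshold only for score/lpr kinds."""

    kind: str
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind in _SCORE_KINDS:
            if self.threshold is None:
                raise ValueError(f"{self.kind} requires a threshold")
            if self.kind == "lpr_below":
                if self.threshold <= 0 or self.threshold != int(self.threshold):
                    raise ValueError("lpr threshold must be a positive integer")
            elif not 0.0 <= self.threshold <= 1.0:
                raise ValueError("MI thresholds must be in [0, 1]")
        elif self.threshold is not None:
            raise ValueError(f"{self.kind} takes no threshold")


@dataclass
class LprMap:
    """Per-record lpr values and the per-publication pair counts behind them."""

    record_lpr: dict[str, int] = field(default_factory=dict)
    pmid_pairs: dict[str, int] = field(default_factory=dict)

    def edge_lpr(self, record_ids: Iterable[str]) -> int:
        """lpr of an edge: minimum over its supporting records."""
        return min(self.record_lpr[rid] for rid in record_ids)


def compute_lpr(interactome: Interactome) -> LprMap:
    """Count distinct spoke-expanded pairs per publication; assign to records.

    Every record must carry a pmid.  A publication cited by records covering
    50 distinct pairs gives each of those records lpr 50; a publication
    unique to one binary record gives lpr 1.
    """
    pairs_by_pmid: dict[str, set[tuple[str, str]]] = {}
    for rec in interactome.records:
        if not rec.pmid:
            raise ValidationError(f"record {rec.record_id!r} has no pmid")
        pairs_by_pmid.setdefault(rec.pmid, set()).update(
            expand_record_edges(rec, "spoke")
        )
    pmid_pairs = {pmid: len(pairs) for pmid, pairs in pairs_by_pmid.items()}
    record_lpr = {rec.record_id: pmid_pairs[rec.pmid] for rec in interactome.records}
    return LprMap(record_lpr=record_lpr, pmid_pairs=pmid_pairs)


def _keeps(
    rec, criterion: FilterCriterion, record_class: Optional[RecordClass], lpr: Optional[LprMap]
) -> bool:
    kind = criterion.kind
    if kind == "lpr_below":
        return lpr.record_lpr[rec.record_id] < criterion.threshold
    if kind == "mi_intact_above":
        return rec.mi_intact is not None and rec.mi_intact > criterion.threshold
    if kind == "mi_psicquic_above":
        return rec.mi_psicquic is not None and rec.mi_psicquic > criterion.threshold
    if kind == "exclude_predicted":
        return not rec.predicted
    # binary_only
    return record_class.assignment[rec.record_id] == "B"


def apply_filter(
    interactome: Interactome,
    criterion: FilterCriterion,
    record_class: Optional[RecordClass] = None,
    lpr: Optional[LprMap] = None,
) -> Interactome:
    """Return a new Interactome keeping records satisfying the criterion."""
    if criterion.kind == "lpr_below" and lpr is None:
        raise ValueError("lpr_below requires a precomputed LprMap")
    if criterion.kind == "binary_only" and record_class is None:
        raise ValueError("binary_only requires a RecordClass")
    return Interactome(
        [rec for rec in interactome.records if _keeps(rec, criterion, record_class, lpr)]
    )


def apply_filters(
    interactome: Interactome,
    criteria: Iterable[FilterCriterion],
    record_class: Optional[RecordClass] = None,
    lpr: Optional[LprMap] = None,
) -> Interactome:
    """Intersection of several criteria, applied in sequence."""
    for criterion in criteria:
        interactome = apply_filter(interactome, criterion, record_class, lpr)
    return interactome


def parse_filter_spec(spec: str) -> list[FilterCriterion]:
    """Parse a comma-separated filter spec, e.g. ``lpr<22,no_predicted``.

    Tokens: ``lpr<T``, ``mi_intact>T``, ``mi_psicquic>T``, ``no_predicted``,
    ``binary_only``.  An empty spec means no filtering.
    """
    out: list[FilterCriterion] = []
    for token in (t.strip() for t in spec.split(",") if t.strip()):
        if token == "no_predicted":
            out.append(FilterCriterion("exclude_predicted"))
        elif token == "binary_only":
            out.append(FilterCriterion("binary_only"))
        elif token.startswith("lpr<"):
            out.append(FilterCriterion("lpr_below", float(token[4:])))
        elif token.startswith("mi_intact>"):
            out.append(FilterCriterion("mi_intact_above", float(token[10:])))
        elif token.startswith("mi_psicquic>"):
            out.append(FilterCriterion("mi_psicquic_above", float(token[12:])))
        else:
            raise ValueError(f"unknown filter token {token!r}")
    return out


def subset_overlap_counts(
    subsets: dict[str, set[str]] | list[tuple[str, set[str]]],
) -> dict:
    """Venn-region counts and pairwise containment for 2-3 named sets.

    Region keys are frozensets of the names whose intersection (and nothing
    else) the region represents.  Containment is reported for every ordered
    name pair.
    """
    items = list(subsets.items()) if isinstance(subsets, dict) else list(subsets)
    if not 2 <= len(items) <= 3:
        raise ValueError("subset_overlap_counts takes 2 or 3 subsets")
    names = [name for name, _ in items]
    sets = {name: set(s) for name, s in items}
    regions: dict[frozenset[str], int] = {}
    for mask in product([False, True], repeat=len(names)):
        if not any(mask):
            continue
        inside = [n for n, m in zip(names, mask) if m]
        outside = [n for n, m in zip(names, mask) if not m]
        region = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        regions[frozenset(inside)] = len(region)
    containment = {
        (a, b): sets[a] <= sets[b] for a in names for b in names if a != b
    }
    return {"names": names, "regions": regions, "containment": containment}
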