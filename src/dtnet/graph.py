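"""Interaction-type classification and graph materialisation.

Two questions dominate how an interaction dataset becomes a graph:

* **What is really binary?**  Records are split into true binary data (B),
  n-ary "complex" data (N), and spoke-represented n-ary data (S) — binary
  records that are in fact one n-ary observation flattened into hub-member
  pairs.  S data is detected by grouping binary records that share
  (source database, publication, detection method) where the method is one
  known to generate n-ary data, and that share at least one protein.

* **How is an n-ary record drawn?**  The spoke model connects one hub
  protein to every other member (n-1 edges); the matrix model connects all
  pairs (n(n-1)/2 edges).

Networks are simple undirected graphs: no self-loops, duplicate supporting
records collapse onto one edge with merged provenance, and degree therefore
counts distinct interaction partners.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .records import COMPLEX, InteractionRecord, Interactome

__all__ = [
    "SGroup",
    "RecordClass",
    "PiNetwork",
    "classify_records_bns",
    "expand_record_edges",
    "build_network",
    "subnetwork_by_label",
    "random_edge_subset",
    "write_edge_list",
]

SPOKE = "spoke"
MATRIX = "matrix"
ALL_CLASSES = frozenset({"B", "N", "S"})


@dataclass(frozen=True)
class SGroup:
    """Binary records collapsed into one spoke-represented n-ary unit."""

    record_ids: frozenset[str]
    members: frozenset[str]
    hub: str
    key: tuple[str, str, str]  # (source_db, pmid, detection_method)


@dataclass
class RecordClass:
    """B/N/S assignment for every record, plus the S-group structure."""

    assignment: dict[str, str]
    s_groups: list[SGroup] = field(default_factory=list)

    def records_in_class(self, cls: str) -> set[str]:
        return {rid for rid, c in self.assignment.items() if c == cls}

    def counts(self) -> dict[str, int]:
        c = Counter(self.assignment.values())
        return {cls: c.get(cls, 0) for cls in ("B", "N", "S")}


@dataclass
class PiNetwork:
    """Simple undirected protein-interaction graph with edge provenance.

    Edges carry a ``records`` attribute: the set of record IDs supporting
    the pair.  ``graph`` is a plain :class:`networkx.Graph` and may be used
    directly for anything this wrapper does not expose.
    """

    graph: nx.Graph
    representation: str = SPOKE
    subset_tag: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()

    def edge_records(self, u: str, v: str) -> frozenset[str]:
        return frozenset(self.graph.edges[u, v]["records"])

    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())


# ---------------------------------------------------------------------------
# B/N/S classification


def _connected_record_groups(
    records: Sequence[InteractionRecord],
) -> list[list[InteractionRecord]]:
    """Group records transitively by shared proteins (union-find)."""
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_protein: dict[str, int] = {}
    for i, rec in enumerate(records):
        for p in rec.interactors:
            if p in by_protein:
                ri, rj = find(i), find(by_protein[p])
                if ri != rj:
                    parent[ri] = rj
            else:
                by_protein[p] = i
    groups: dict[int, list[InteractionRecord]] = defaultdict(list)
    for i, rec in enumerate(records):
        groups[find(i)].append(rec)
    return list(groups.values())


def _group_hub(records: Sequence[InteractionRecord]) -> str:
    """Hub of an S-group: the protein common to all records if one exists,
    else the most frequent member; ties break lexicographically."""
    counts = Counter(p for rec in records for p in set(rec.interactors))
    return min(counts, key=lambda p: (-counts[p], p))


def classify_records_bns(
    interactome: Interactome, nary_methods: Iterable[str]
) -> RecordClass:
    """Partition records into B (true binary), N (complex) and S classes.

    Binary records sharing (source_db, pmid, detection_method) with the
    method in ``nary_methods``, and connected through shared proteins, are
    collapsed into S-groups; a lone binary record under an n-ary key has
    nothing to group with and stays B.
    """
    nary = set(nary_methods)
    assignment: dict[str, str] = {}
    s_groups: list[SGroup] = []
    candidates: dict[tuple[str, str, str], list[InteractionRecord]] = defaultdict(list)
    for rec in interactome.records:
        if rec.record_kind == COMPLEX:
            assignment[rec.record_id] = "N"
        elif rec.detection_method in nary:
            candidates[(rec.source_db, rec.pmid, rec.detection_method)].append(rec)
        else:
            assignment[rec.record_id] = "B"
    for key in sorted(candidates):
        for group in _connected_record_groups(candidates[key]):
            if len(group) == 1:
                assignment[group[0].record_id] = "B"
                continue
            members = frozenset(p for rec in group for p in rec.interactors)
            s_groups.append(
                SGroup(
                    record_ids=frozenset(rec.record_id for rec in group),
                    members=members,
                    hub=_group_hub(group),
                    key=key,
                )
            )
            for rec in group:
                assignment[rec.record_id] = "S"
    s_groups.sort(key=lambda g: min(g.record_ids))
    return RecordClass(assignment=assignment, s_groups=s_groups)


# ---------------------------------------------------------------------------
# edge expansion


def _expand_members(
    members: Sequence[str], hub: str, mode: str
) -> set[tuple[str, str]]:
    if len(members) < 2:
        raise ValueError(f"cannot expand a record with {len(members)} members")
    if mode == SPOKE:
        pairs = {(hub, m) for m in members if m != hub}
    elif mode == MATRIX:
        uniq = sorted(set(members))
        pairs = {
            (uniq[i], uniq[j])
            for i in range(len(uniq))
            for j in range(i + 1, len(uniq))
        }
    else:
        raise ValueError(f"unknown representation {mode!r}")
    return {tuple(sorted(p)) for p in pairs if p[0] != p[1]}


def expand_record_edges(
    item: Union[InteractionRecord, SGroup], mode: str
) -> set[tuple[str, str]]:
    """Unordered protein pairs produced by one record (or S-group) under
    spoke or matrix representation; identical-endpoint pairs are dropped.

    For a size-n member set: spoke yields n-1 pairs, matrix n(n-1)/2;
    binary records give their single pair in either mode.
    """
    if isinstance(item, SGroup):
        return _expand_members(sorted(item.members), item.hub, mode)
    return _expand_members(item.interactors, item.hub, mode)


# ---------------------------------------------------------------------------
# network construction


def build_network(
    interactome: Interactome,
    record_class: RecordClass,
    representation: str = SPOKE,
    classes: Iterable[str] = ALL_CLASSES,
    subset_tag: str = "",
) -> PiNetwork:
    """Materialise a simple graph from the records whose class is selected.

    S-assigned records are expanded once per S-group (via the group's
    derived member set and hub), never individually.  Duplicate pairs merge
    with provenance union; nodes are edge endpoints only, so proteins with
    nothing but self-interactions vanish.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be a non-empty subset of {B, N, S}")
    if unknown := classes - ALL_CLASSES:
        raise ValueError(f"unknown record classes: {sorted(unknown)}")
    edge_records: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in interactome.records:
        cls = record_class.assignment[rec.record_id]
        if cls == "S" or cls not in classes:
            continue
        for pair in expand_record_edges(rec, representation):
            edge_records[pair].add(rec.record_id)
    if "S" in classes:
        for group in record_class.s_groups:
            for pair in expand_record_edges(group, representation):
                edge_records[pair].update(group.record_ids)
    g = nx.Graph()
    for (u, v), rids in edge_records.items():
        g.add_edge(u, v, records=frozenset(rids))
    return PiNetwork(graph=g, representation=representation, subset_tag=subset_tag)


def subnetwork_by_label(
    network: PiNetwork, members: Iterable[str], mode: str = "only"
) -> PiNetwork:
    """Induced subgraph on (or excluding) a labelled protein set.

    Unlike plain induction, nodes that end up isolated are kept: the
    drug-target subnetwork's average degree is taken over *all* labelled
    proteins present in the parent network, including those with no
    within-group edge.
    """
    members = set(members)
    if mode == "only":
        keep = members & network.nodes
    elif mode == "exclude":
        keep = network.nodes - members
    else:
        raise ValueError(f"mode must be 'only' or 'exclude', got {mode!r}")
    sub = network.graph.subgraph(keep).copy()
    sub.add_nodes_from(keep)
    return PiNetwork(
        graph=sub,
        representation=network.representation,
        subset_tag=f"{network.subset_tag}|{mode}_label".lstrip("|"),
    )


def random_edge_subset(network: PiNetwork, keep_fraction: float, seed: int) -> PiNetwork:
    """Keep a uniform random fraction of edges (provenance preserved).

    Used as an 'arbitrary subset' control against reliability-motivated
    filtering: the node set shrinks to the surviving edges' endpoints.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(network.graph.edges())
    n_keep = int(round(keep_fraction * len(edges)))
    idx = rng.choice(len(edges), size=n_keep, replace=False) if edges else []
    g = nx.Graph()
    for i in sorted(idx):
        u, v = edges[i]
        g.add_edge(u, v, records=network.graph.edges[u, v]["records"])
    return PiNetwork(
        graph=g,
        representation=network.representation,
        subset_tag=f"{network.subset_tag}|random{keep_fraction:g}".lstrip("|"),
    )


def write_edge_list(network: PiNetwork, path: str | Path) -> None:
    """Export edges as TSV: endpoints, support count, supporting record IDs."""
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tn_supporting_records\trecord_ids\n")
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges()):
            rids = sorted(network.graph.edges[u, v]["records"])
            fh.write(f"{u}\t{v}\t{len(rids)}\t{'|'.join(rids)}\n")
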