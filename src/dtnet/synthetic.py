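"""Synthetic labelled interactomes with the structure the analysis assumes.

Real consolidated interactomes (iRefIndex-style) have: a heavy-tailed
degree distribution; n-ary complex records alongside true binary data;
spoke-represented n-ary data hiding among the binary records (same source
database, publication and n-ary-generating detection method, sharing a hub
protein); a mix of high-throughput publications contributing hundreds of
pairs and low-throughput papers contributing a handful; orthology-predicted
records; partial confidence-score coverage; drug-target annotations biased
toward high-degree proteins; pathway memberships enriched for drug targets;
disease-protein annotations partially overlapping the drug targets; and a
small set of withdrawn-drug targets sitting at high centrality.

The generator plants each of these features with an explicit, recoverable
parameter and returns the ground truth alongside the dataset, so the
classification, filtering and evaluation machinery can be held against
known answers.  Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .graph import PiNetwork, build_network, classify_records_bns
from .metrics import compute_metric
from .records import (
    COMPLEX,
    InteractionRecord,
    Interactome,
    LabelSet,
    PathwayTable,
    write_gmt,
    write_labels,
    write_mitab_dialect,
)

__all__ = [
    "NARY_METHODS",
    "BINARY_METHODS",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_interactome",
    "plant_degree_biased_labels",
    "assign_provenance",
]

#: detection methods treated as n-ary-generating (spoke-representation
#: suspects); the generator stamps them on complex-derived records and the
#: classifier is configured with the same list.
NARY_METHODS = frozenset({"tap", "coip"})
BINARY_METHODS = ("two_hybrid", "xray", "crosslink")
SOURCE_DBS = ("intact", "biogrid", "mint", "hprd", "dip")
PREDICTED_DB = "ophid"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the standing conditions.

    The backbone is a preferential-attachment graph (right-skewed degree
    distribution); complexes are sampled over its nodes and emitted either
    as true n-ary records or as spoke-represented binary groups; labels are
    planted with selection weight proportional to degree^degree_bias.
    """

    n_proteins: int = 5000
    attachment_edges_per_node: int = 4
    n_complexes: int = 300
    complex_size_p: float = 0.35     # truncated geometric, support [min, max]
    complex_size_min: int = 3
    complex_size_max: int = 20
    s_fraction: float = 0.3          # fraction of complexes emitted as S-groups
    n_drug_targets: int = 300
    degree_bias: float = 1.5         # beta: label weight ~ degree^beta
    n_htp_pubs: int = 20
    n_ltp_pubs: int = 2000
    htp_assignment_fraction: float = 0.5
    predicted_fraction: float = 0.15
    score_noise: float = 0.15        # sigma of MI scores around their mean
    score_missing_fraction: float = 0.3
    n_pathways: int = 150
    pathway_size_p: float = 0.08
    pathway_size_min: int = 5
    pathway_size_max: int = 80
    pathway_dt_enrichment: float = 4.0   # odds multiplier for drug targets
    n_disease_proteins: Optional[int] = None  # default: 1.7 * n_drug_targets
    disease_overlap: float = 0.35    # fraction of drug targets also disease
    withdrawn_fraction: float = 0.1  # of drug targets, drawn from top-BC decile
    cancer_fraction: float = 0.25    # of drug targets
    cancer_degree_bias: float = 1.0  # extra degree bias within drug targets
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "s_fraction": self.s_fraction,
            "htp_assignment_fraction": self.htp_assignment_fraction,
            "predicted_fraction": self.predicted_fraction,
            "score_missing_fraction": self.score_missing_fraction,
            "disease_overlap": self.disease_overlap,
            "withdrawn_fraction": self.withdrawn_fraction,
            "cancer_fraction": self.cancer_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.degree_bias < 0 or self.cancer_degree_bias < 0:
            raise ValueError("degree bias must be >= 0")
        if self.n_drug_targets > self.n_proteins:
            raise ValueError("n_drug_targets exceeds n_proteins")
        if self.complex_size_max > self.n_proteins:
            raise ValueError("complex size exceeds protein count")
        if not 3 <= self.complex_size_min <= self.complex_size_max:
            raise ValueError("complex sizes must satisfy 3 <= min <= max")
        if self.n_htp_pubs + self.n_ltp_pubs < 1:
            raise ValueError("need at least one publication")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted parameters and true assignments, for held-out assertions."""

    config: GeneratorConfig
    true_class: dict[str, str]                 # record_id -> B/N/S
    s_groups: list[frozenset[str]]             # true S-group record-ID sets
    htp_pubs: set[str]
    ltp_pubs: set[str]

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "true_class": dict(sorted(self.true_class.items())),
            "s_groups": [sorted(g) for g in self.s_groups],
            "htp_pubs": sorted(self.htp_pubs),
            "ltp_pubs": sorted(self.ltp_pubs),
        }


@dataclass
class SyntheticDataset:
    interactome: Interactome
    labels: LabelSet
    pathways: PathwayTable
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit dialect TSV, label TSV, GMT pathways and ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": outdir / "interactions.tsv",
            "labels": outdir / "labels.tsv",
            "pathways": outdir / "pathways.gmt",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_mitab_dialect(self.interactome, paths["interactions"])
        write_labels(self.labels, paths["labels"])
        write_gmt(self.pathways, paths["pathways"])
        paths["ground_truth"].write_text(
            json.dumps(self.truth.to_json_dict(), indent=1, sort_keys=True)
        )
        return paths


# ---------------------------------------------------------------------------
# sampling helpers


def _weighted_sample(
    rng: np.random.Generator, items: Sequence[str], weights: np.ndarray, k: int
) -> set[str]:
    """Weighted sampling without replacement (Gumbel top-k keys)."""
    if k > len(items):
        raise ValueError(f"cannot sample {k} from {len(items)} items")
    if k == len(items):
        return set(items)
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=len(items))
    idx = np.argpartition(-keys, k)[:k]
    return {items[i] for i in idx}


def _trunc_geometric(
    rng: np.random.Generator, p: float, lo: int, hi: int, size: int
) -> np.ndarray:
    draws = lo + rng.geometric(p, size=size) - 1
    return np.minimum(draws, hi)


def plant_degree_biased_labels(
    network: PiNetwork, n_labels: int, beta: float, seed: int
) -> set[str]:
    """Sample labels without replacement with weight degree(v)^beta.

    beta = 0 is uniform sampling; large beta concentrates labels on hubs.
    Deterministic for a fixed seed.
    """
    nodes = sorted(network.nodes)
    if n_labels > len(nodes):
        raise ValueError(f"cannot plant {n_labels} labels on {len(nodes)} nodes")
    degrees = np.array([network.graph.degree(v) for v in nodes], dtype=float)
    rng = np.random.default_rng(seed)
    return _weighted_sample(rng, nodes, degrees**beta, n_labels)


def assign_provenance(
    records: Sequence[InteractionRecord],
    n_htp: int,
    n_ltp: int,
    htp_fraction: float,
    seed: int,
) -> list[InteractionRecord]:
    """Fill empty pmid/source_db/detection_method fields on records.

    Each record with an empty pmid is sent to the high-throughput class
    with probability ``htp_fraction`` and the low-throughput class
    otherwise; within a class, records are spread over the class's
    publications by shuffled round-robin, so realised per-publication pair
    counts are ~|class records|/n_pubs — large for ``HT*`` IDs, small for
    ``LT*`` IDs (exactly one record per publication when a class has as
    many publications as records).  Deterministic per seed.
    """
    if htp_fraction > 0 and n_htp < 1:
        raise ValueError("htp_fraction > 0 requires n_htp >= 1")
    if htp_fraction < 1 and n_ltp < 1:
        raise ValueError("htp_fraction < 1 requires n_ltp >= 1")
    rng = np.random.default_rng(seed)
    needs_pmid = [i for i, rec in enumerate(records) if not rec.pmid]
    is_htp = rng.random(len(needs_pmid)) < htp_fraction
    pmids: dict[int, str] = {}
    for cls, prefix, n_pubs in ((True, "HT", n_htp), (False, "LT", n_ltp)):
        members = [i for i, h in zip(needs_pmid, is_htp) if h == cls]
        if not members:
            continue
        order = rng.permutation(len(members))
        pubs = rng.permutation(n_pubs)
        for pos, i in zip(order, members):
            pmids[i] = f"pmid:{prefix}{pubs[pos % n_pubs]}"
    out: list[InteractionRecord] = []
    for i, rec in enumerate(records):
        fields: dict = {}
        if i in pmids:
            fields["pmid"] = pmids[i]
        if not rec.source_db:
            fields["source_db"] = SOURCE_DBS[rng.integers(len(SOURCE_DBS))]
        if not rec.detection_method:
            fields["detection_method"] = BINARY_METHODS[
                rng.integers(len(BINARY_METHODS))
            ]
        out.append(rec.with_fields(**fields) if fields else rec)
    return out


# ---------------------------------------------------------------------------
# full generator


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def generate_interactome(
    config: GeneratorConfig,
) -> SyntheticDataset:
    """Generate a labelled interactome, pathways and ground truth.

    Pipeline: preferential-attachment binary backbone; complexes emitted as
    n-ary records or spoke-represented S-groups (each S-group under its own
    dedicated publication, as a small study reporting one complex);
    publication assignment splitting records over HTP/LTP papers; predicted
    flags; MI scores with means raised for multi-record-supported pairs;
    degree-biased drug-target labels; drug-target-enriched pathways;
    disease labels overlapping the targets; withdrawn targets drawn from
    the top betweenness decile of the drug targets; a degree-biased cancer
    subset of the targets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins = [_protein_id(i) for i in range(config.n_proteins)]

    # (1) heavy-tailed binary backbone
    backbone = nx.barabasi_albert_graph(
        config.n_proteins,
        config.attachment_edges_per_node,
        seed=int(rng.integers(2**31)),
    )
    records: list[InteractionRecord] = []
    for i, (u, v) in enumerate(sorted(backbone.edges())):
        records.append(
            InteractionRecord(
                record_id=f"B{i:06d}",
                interactors=(proteins[u], proteins[v]),
            )
        )

    # (2) complexes: true n-ary records or spoke-represented S-groups
    truth_class: dict[str, str] = {rec.record_id: "B" for rec in records}
    s_groups: list[frozenset[str]] = []
    s_pub_ids: set[str] = set()
    sizes = _trunc_geometric(
        rng, config.complex_size_p, config.complex_size_min,
        config.complex_size_max, config.n_complexes,
    )
    s_records: list[InteractionRecord] = []
    for ci, size in enumerate(sizes):
        members = [proteins[j] for j in rng.choice(config.n_proteins, int(size), replace=False)]
        method = ("tap", "coip")[rng.integers(2)]
        db = SOURCE_DBS[rng.integers(len(SOURCE_DBS))]
        if rng.random() < config.s_fraction:
            pmid = f"pmid:S{ci}"
            s_pub_ids.add(pmid)
            hub = members[0]
            group_ids = []
            for j, m in enumerate(members[1:]):
                rid = f"S{ci:05d}.{j}"
                group_ids.append(rid)
                s_records.append(
                    InteractionRecord(
                        record_id=rid,
                        interactors=(hub, m),
                        source_db=db,
                        pmid=pmid,
                        detection_method=method,
                    )
                )
                truth_class[rid] = "S"
            s_groups.append(frozenset(group_ids))
        else:
            rid = f"C{ci:05d}"
            records.append(
                InteractionRecord(
                    record_id=rid,
                    interactors=tuple(members),
                    record_kind=COMPLEX,
                    hub_index=0,
                    source_db=db,
                    detection_method=method,
                )
            )
            truth_class[rid] = "N"

    # (3) publications: backbone + complex records over HTP/LTP papers
    records = assign_provenance(
        records,
        config.n_htp_pubs,
        config.n_ltp_pubs,
        config.htp_assignment_fraction,
        seed=int(rng.integers(2**31)),
    )
    records.extend(s_records)
    htp_pubs = {r.pmid for r in records if r.pmid.startswith("pmid:HT")}
    ltp_pubs = {r.pmid for r in records if not r.pmid.startswith("pmid:HT")}

    # (4) predicted flags on true binary backbone records
    flagged = []
    for rec in records:
        if rec.record_id.startswith("B") and rng.random() < config.predicted_fraction:
            rec = rec.with_fields(predicted=True, source_db=PREDICTED_DB)
        flagged.append(rec)
    records = flagged

    # (5) MI scores: mean rises with multi-record pair support
    pair_support: dict[tuple[str, str], int] = {}
    spoke_pairs: list[set[tuple[str, str]]] = []
    from .graph import expand_record_edges  # local import avoids cycle at load

    for rec in records:
        pairs = expand_record_edges(rec, "spoke")
        spoke_pairs.append(pairs)
        for pair in pairs:
            pair_support[pair] = pair_support.get(pair, 0) + 1
    scored = []
    for rec, pairs in zip(records, spoke_pairs):
        support = max(pair_support[p] for p in pairs)
        mu = 0.40 + 0.15 * min(support - 1, 2)
        mi_i = mi_p = None
        if rng.random() >= config.score_missing_fraction:
            mi_i = float(np.clip(rng.normal(mu, config.score_noise), 0.0, 1.0))
        if rng.random() >= config.score_missing_fraction:
            mi_p = float(np.clip(rng.normal(mu, config.score_noise), 0.0, 1.0))
        scored.append(rec.with_fields(mi_intact=mi_i, mi_psicquic=mi_p))
    records = scored

    interactome = Interactome(records)

    # (6) degree-biased drug targets on the full spoke network
    record_class = classify_records_bns(interactome, NARY_METHODS)
    network = build_network(interactome, record_class, "spoke")
    drug_targets = plant_degree_biased_labels(
        network, config.n_drug_targets, config.degree_bias,
        seed=int(rng.integers(2**31)),
    )

    # (7) pathways enriched for drug targets (odds multiplier)
    pathways = PathwayTable()
    weights = np.array(
        [config.pathway_dt_enrichment if p in drug_targets else 1.0 for p in proteins]
    )
    psizes = _trunc_geometric(
        rng, config.pathway_size_p, config.pathway_size_min,
        config.pathway_size_max, config.n_pathways,
    )
    for pi, size in enumerate(psizes):
        pid = f"PW{pi:04d}"
        pathways.pathways[pid] = _weighted_sample(rng, proteins, weights, int(size))
        pathways.descriptions[pid] = f"synthetic pathway {pi}"

    # (8) disease proteins partially overlapping drug targets
    n_disease = config.n_disease_proteins
    if n_disease is None:
        n_disease = int(round(1.7 * config.n_drug_targets))
    n_overlap = min(int(round(config.disease_overlap * config.n_drug_targets)), n_disease)
    dt_sorted = sorted(drug_targets)
    non_dt = sorted(set(proteins) - drug_targets)
    disease = _weighted_sample(rng, dt_sorted, np.ones(len(dt_sorted)), n_overlap)
    n_rest = min(n_disease - n_overlap, len(non_dt))
    disease |= _weighted_sample(rng, non_dt, np.ones(len(non_dt)), n_rest)

    labels = LabelSet({"drug_target": drug_targets, "disease": disease})

    # (9) withdrawn targets from the top betweenness decile of drug targets
    n_withdrawn = int(round(config.withdrawn_fraction * len(drug_targets)))
    if n_withdrawn > 0:
        bc = compute_metric(network, "betweenness")
        dts_in_net = [v for v in dt_sorted if v in bc]
        ranked = sorted(dts_in_net, key=lambda v: (-bc[v], v))
        top_k = max(n_withdrawn, int(np.ceil(0.1 * len(ranked))))
        candidates = ranked[:top_k]
        labels.labels["withdrawn_dt"] = _weighted_sample(
            rng, candidates, np.ones(len(candidates)), min(n_withdrawn, len(candidates))
        )
    else:
        labels.labels["withdrawn_dt"] = set()

    # (10) cancer drug targets: degree-biased subset of the targets
    n_cancer = int(round(config.cancer_fraction * len(drug_targets)))
    deg = network.degree()
    cancer_w = np.array(
        [float(deg.get(v, 0) + 1) ** config.cancer_degree_bias for v in dt_sorted]
    )
    labels.labels["cancer_dt"] = _weighted_sample(rng, dt_sorted, cancer_w, n_cancer)

    truth = GroundTruth(
        config=config,
        true_class=truth_class,
        s_groups=s_groups,
        htp_pubs=htp_pubs,
        ltp_pubs=ltp_pubs,
    )
    return SyntheticDataset(
        interactome=interactome, labels=labels, pathways=pathways, truth=truth
    )
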