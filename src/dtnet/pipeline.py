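"""Full-study orchestration: one configured, logged, reproducible run.

A run takes an interactome (read from files or generated synthetically),
builds the full network and a set of named reliability subsets, and emits
the complete report bundle as plain TSV tables:

* degree/centrality summaries per label group, per subset;
* connected-component reports with labelled-node counts;
* B/N/S interaction-type coverage;
* an AUC matrix (metrics x subsets x label sets);
* degree-change comparisons of each subset against the full network;
* Venn overlap counts of the reliability subsets;
* rank-bin over-representation tables per subset and metric;
* pathway-membership statistics and pathway-centrality AUCs (with and
  without zero-pathway proteins in the universe);
* drug-target -> disease-protein shortest-path distance profiles;
* a withdrawn-vs-other drug-target centrality comparison;
* a manifest with the config hash and seed, making reruns byte-identical.

Each subset's metrics are computed within that subset's own network, not
by restricting full-network metrics: every row of the AUC matrix is its
own graph.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment import bin_overrepresentation, make_rank_bins, pathway_centrality_map, roc_curve
from .graph import PiNetwork, build_network, classify_records_bns, subnetwork_by_label
from .metrics import (
    component_report,
    compute_metric,
    metric_summary,
    nearest_label_distance,
    ranksum_compare,
)
from .records import (
    Interactome,
    LabelSet,
    PathwayTable,
    read_gmt,
    read_labels,
    read_mitab_dialect,
)
from .reliability import apply_filters, compute_lpr, parse_filter_spec, subset_overlap_counts
from .synthetic import NARY_METHODS, GeneratorConfig, generate_interactome

__all__ = ["SubsetDef", "RunConfig", "RunResult", "run_pipeline", "DEFAULT_SUBSETS"]

log = logging.getLogger("dtnet.pipeline")


@dataclass(frozen=True)
class SubsetDef:
    """A named subset: a filter spec and/or a B/N/S class selection."""

    name: str
    filter_spec: str = ""
    classes: tuple[str, ...] = ("B", "N", "S")


DEFAULT_SUBSETS = (
    SubsetDef("full"),
    SubsetDef("binary_only", "binary_only", classes=("B",)),
    SubsetDef("no_predicted", "no_predicted"),
    SubsetDef("ltp", "lpr<22"),
    SubsetDef("mi_intact", "mi_intact>0.6"),
    SubsetDef("mi_psicquic", "mi_psicquic>0.7"),
)


@dataclass
class RunConfig:
    # either file inputs ...
    interactions: Optional[str] = None
    labels: Optional[str] = None
    pathways: Optional[str] = None
    # ... or synthetic mode
    generator: Optional[GeneratorConfig] = None

    representation: str = "spoke"
    subsets: tuple[SubsetDef, ...] = DEFAULT_SUBSETS
    metrics: tuple[str, ...] = ("degree", "betweenness", "closeness")
    min_bin_size: int = 200
    alpha: float = 0.05
    roc_labels: tuple[str, ...] = ("drug_target",)
    nary_methods: tuple[str, ...] = tuple(sorted(NARY_METHODS))
    outdir: str = "dtnet_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.subsets:
            raise ValueError("at least one subset (e.g. 'full') is required")
        if not self.metrics:
            raise ValueError("at least one metric is required")
        if self.representation not in ("spoke", "matrix"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.generator is None and self.interactions is None:
            raise ValueError("either 'interactions' or 'generator' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "generator" in raw and raw["generator"] is not None:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if "subsets" in raw:
            raw["subsets"] = tuple(
                SubsetDef(
                    name=s["name"],
                    filter_spec=s.get("filter_spec", ""),
                    classes=tuple(s.get("classes", ("B", "N", "S"))),
                )
                for s in raw["subsets"]
            )
        for key in ("metrics", "roc_labels", "nary_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    auc_table: pd.DataFrame
    summary_table: pd.DataFrame
    component_table: pd.DataFrame
    coverage_table: pd.DataFrame
    degree_change_table: pd.DataFrame
    overlap_table: pd.DataFrame
    distance_table: pd.DataFrame
    pathway_table: Optional[pd.DataFrame]
    withdrawn_table: Optional[pd.DataFrame]
    manifest: dict


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _subset_interactome(
    full: Interactome, sdef: SubsetDef, record_class, lpr
) -> Interactome:
    criteria = parse_filter_spec(sdef.filter_spec)
    return apply_filters(full, criteria, record_class=record_class, lpr=lpr)


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ----- inputs ---------------------------------------------------------
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        dataset = generate_interactome(gen)
        interactome, labels, pathways = (
            dataset.interactome,
            dataset.labels,
            dataset.pathways,
        )
        dataset.write(outdir / "synthetic_input")
    else:
        interactome = read_mitab_dialect(config.interactions)
        labels = read_labels(config.labels) if config.labels else LabelSet()
        pathways = read_gmt(config.pathways) if config.pathways else None
        if isinstance(pathways, PathwayTable) and len(pathways) == 0:
            pathways = None

    for name in config.roc_labels:
        if name not in labels:
            raise ValueError(f"ROC label {name!r} not present in the label set")
    drug_targets = labels.get("drug_target", set())

    log.info("interactome: %d records, %d proteins", len(interactome), len(interactome.universe))

    # ----- full-network groundwork ---------------------------------------
    nary = set(config.nary_methods)
    full_class = classify_records_bns(interactome, nary)
    lpr = compute_lpr(interactome)

    auc_rows, summary_rows, component_rows, change_rows, distance_rows = [], [], [], [], []
    subset_records: dict[str, set[str]] = {}
    full_degree = None
    networks: dict[str, PiNetwork] = {}

    for sdef in config.subsets:
        sub_int = _subset_interactome(interactome, sdef, full_class, lpr)
        subset_records[sdef.name] = sub_int.record_ids()
        sub_class = classify_records_bns(sub_int, nary)
        classes = set(sdef.classes)
        network = build_network(
            sub_int, sub_class, config.representation, classes, subset_tag=sdef.name
        )
        networks[sdef.name] = network
        log.info(
            "subset %-14s %6d records %6d nodes %7d edges",
            sdef.name, len(sub_int), network.n_nodes, network.n_edges,
        )
        sub_dir = outdir / "subsets" / sdef.name
        degenerate = network.n_nodes == 0
        metric_maps = {}
        for metric in config.metrics:
            if degenerate:
                continue
            mm = compute_metric(network, metric)
            metric_maps[metric] = mm
            _write(
                pd.DataFrame(
                    sorted(mm.items()), columns=["protein_id", "value"]
                ),
                sub_dir / "metrics" / f"{metric}.tsv",
            )
            # summaries per label group (all / each label / complement of drug_target)
            groups = {"all": None}
            for lname, members in labels.labels.items():
                groups[lname] = members
            if drug_targets:
                groups["non_drug_target"] = set(mm) - drug_targets
            for gname, members in groups.items():
                keys = set(mm) if members is None else (set(mm) & set(members))
                if not keys:
                    continue
                s = metric_summary(mm, keys)
                summary_rows.append(
                    {"subset": sdef.name, "metric": metric, "group": gname, **s.to_dict()}
                )
            # rank-bin over-representation of drug targets
            if drug_targets and len(mm) >= config.min_bin_size and (set(mm) & drug_targets):
                bins = make_rank_bins(mm, config.min_bin_size)
                enr = bin_overrepresentation(bins, drug_targets, config.alpha)
                _write(enr.to_frame(), sub_dir / "enrichment" / f"{metric}.tsv")
            # ROC per requested label
            for lname in config.roc_labels:
                pos = set(labels[lname]) & set(mm)
                if 0 < len(pos) < len(mm):
                    roc = roc_curve(mm, pos)
                    _write(roc.to_frame(), sub_dir / "roc" / f"{metric}_{lname}.tsv")
                    auc_rows.append(
                        {
                            "subset": sdef.name,
                            "metric": metric,
                            "label": lname,
                            "n_proteins": len(mm),
                            "n_positives": roc.n_pos,
                            "auc": roc.auc,
                            "degenerate": False,
                        }
                    )
                else:
                    auc_rows.append(
                        {
                            "subset": sdef.name,
                            "metric": metric,
                            "label": lname,
                            "n_proteins": len(mm),
                            "n_positives": len(pos),
                            "auc": float("nan"),
                            "degenerate": True,
                        }
                    )
        if degenerate:
            for metric in config.metrics:
                for lname in config.roc_labels:
                    auc_rows.append(
                        {
                            "subset": sdef.name,
                            "metric": metric,
                            "label": lname,
                            "n_proteins": 0,
                            "n_positives": 0,
                            "auc": float("nan"),
                            "degenerate": True,
                        }
                    )
            continue

        # drug-target / non-drug-target subnetworks (full network only):
        # isolated labelled nodes are kept, so the group's average degree is
        # taken over every labelled protein present in the parent network
        if sdef.name == "full" and drug_targets and "degree" in metric_maps:
            for gname, mode in (
                ("drug_target_subnetwork", "only"),
                ("non_drug_target_subnetwork", "exclude"),
            ):
                sub = subnetwork_by_label(network, drug_targets, mode)
                if sub.n_nodes:
                    s = metric_summary({v: float(d) for v, d in sub.graph.degree()})
                    summary_rows.append(
                        {"subset": sdef.name, "metric": "degree", "group": gname, **s.to_dict()}
                    )

        # component report
        rep = component_report(network, labels)
        row = {
            "subset": sdef.name,
            "n_components": len(rep.components),
            "giant_size": rep.sizes[0] if rep.sizes else 0,
            "n_proteins_disconnected": rep.n_disconnected_proteins,
        }
        for lname in labels.labels:
            row[f"disconnected_{lname}"] = rep.disconnected.get(lname, 0)
        component_rows.append(row)

        # degree change vs full (drug targets vs the rest)
        if sdef.name == "full":
            full_degree = metric_maps.get("degree")
        # disease distances
        if drug_targets and "disease" in labels:
            prof = nearest_label_distance(network, drug_targets, labels["disease"])
            hist = prof.histogram()
            for dist, count in hist.items():
                distance_rows.append(
                    {"subset": sdef.name, "distance": dist, "n_drug_targets": count}
                )
            distance_rows.append(
                {"subset": sdef.name, "distance": "Inf", "n_drug_targets": len(prof.unreachable)}
            )

    # degree change table needs the full network's degree map
    if full_degree is not None and drug_targets:
        for sdef in config.subsets:
            if sdef.name == "full" or networks[sdef.name].n_nodes == 0:
                continue
            sub_deg = {
                v: float(d) for v, d in networks[sdef.name].graph.degree()
                if v in full_degree
            }
            group_a = drug_targets & set(full_degree)
            group_b = set(full_degree) - drug_targets
            if not group_a or not group_b:
                continue
            from .metrics import degree_change_report

            rep = degree_change_report(full_degree, sub_deg, group_a, group_b)
            change_rows.append(
                {
                    "subset": sdef.name,
                    "mean_change_drug_targets": rep.mean_change_a,
                    "mean_change_non_drug_targets": rep.mean_change_b,
                    "wilcoxon_p": rep.p_value,
                }
            )

    # ----- B/N/S coverage (class networks of the full interactome) -------
    coverage_rows = []
    full_net = networks.get("full")
    for cls_name, classes in (("B", ("B",)), ("N", ("N",)), ("S", ("S",)), ("full", ("B", "N", "S"))):
        net = (
            full_net
            if cls_name == "full" and full_net is not None
            else build_network(interactome, full_class, config.representation, classes)
        )
        if net.n_nodes == 0:
            coverage_rows.append(
                {"network": cls_name, "n_proteins": 0, "n_edges": 0,
                 "pct_all_drug_targets": 0.0, "pct_drug_targets_in_set": 0.0,
                 "avg_degree": float("nan"), "max_degree": 0}
            )
            continue
        deg = net.degree()
        dts_in = drug_targets & net.nodes
        dts_total = len(drug_targets & (networks["full"].nodes if "full" in networks else interactome.universe)) or len(drug_targets)
        coverage_rows.append(
            {
                "network": cls_name,
                "n_proteins": net.n_nodes,
                "n_edges": net.n_edges,
                "pct_all_drug_targets": 100.0 * len(dts_in) / dts_total if dts_total else 0.0,
                "pct_drug_targets_in_set": 100.0 * len(dts_in) / net.n_nodes,
                "avg_degree": sum(deg.values()) / net.n_nodes,
                "max_degree": max(deg.values()),
            }
        )

    # ----- subset overlap (Venn of reliability subsets) -------------------
    overlap_names = [
        n for n in ("mi_psicquic", "ltp", "no_predicted") if n in subset_records
    ]
    overlap_rows = []
    if len(overlap_names) >= 2:
        venn = subset_overlap_counts({n: subset_records[n] for n in overlap_names[:3]})
        for region, count in sorted(venn["regions"].items(), key=lambda kv: sorted(kv[0])):
            overlap_rows.append({"region": "&".join(sorted(region)), "n_records": count})
        for (a, b), contained in sorted(venn["containment"].items()):
            overlap_rows.append(
                {"region": f"{a}<={b}", "n_records": int(contained)}
            )

    # ----- pathway centrality ---------------------------------------------
    pathway_df = None
    if pathways is not None and drug_targets and full_net is not None:
        universe = full_net.nodes
        prows = []
        for include_zero in (False, True):
            pc = pathway_centrality_map(pathways, universe, include_zero)
            dts = drug_targets & set(pc)
            non = set(pc) - drug_targets
            row = {
                "universe": "zero_or_more" if include_zero else "one_or_more",
                "n_proteins": len(pc),
                "avg_pathways_drug_target": metric_summary(pc, dts).mean if dts else float("nan"),
                "avg_pathways_non_drug_target": metric_summary(pc, non).mean if non else float("nan"),
                "max_pathways_drug_target": metric_summary(pc, dts).max if dts else float("nan"),
                "max_pathways_non_drug_target": metric_summary(pc, non).max if non else float("nan"),
            }
            if dts and non:
                row["auc"] = roc_curve(pc, dts).auc
            else:
                row["auc"] = float("nan")
            prows.append(row)
        pathway_df = pd.DataFrame(prows)
        _write(pathway_df, outdir / "pathway_centrality.tsv")

    # ----- withdrawn-target centrality ------------------------------------
    withdrawn_df = None
    withdrawn = labels.get("withdrawn_dt", set())
    if withdrawn and drug_targets and full_net is not None and "betweenness" in config.metrics:
        bc = compute_metric(full_net, "betweenness")
        wd = [bc[v] for v in withdrawn & set(bc)]
        other = [bc[v] for v in (drug_targets - withdrawn) & set(bc)]
        if wd and other:
            res = ranksum_compare(wd, other)
            withdrawn_df = pd.DataFrame(
                [
                    {
                        "group": "withdrawn_dt",
                        "n": len(wd),
                        "mean_bc": res.mean_a,
                        "max_bc": max(wd),
                        "wilcoxon_p_vs_other": res.p_value,
                    },
                    {
                        "group": "other_dt",
                        "n": len(other),
                        "mean_bc": res.mean_b,
                        "max_bc": max(other),
                        "wilcoxon_p_vs_other": res.p_value,
                    },
                ]
            )
            _write(withdrawn_df, outdir / "withdrawn_centrality.tsv")

    # ----- assemble and write the bundle ----------------------------------
    auc_table = pd.DataFrame(auc_rows)
    summary_table = pd.DataFrame(summary_rows)
    component_table = pd.DataFrame(component_rows)
    coverage_table = pd.DataFrame(coverage_rows)
    degree_change_table = pd.DataFrame(change_rows)
    overlap_table = pd.DataFrame(overlap_rows)
    distance_table = pd.DataFrame(distance_rows)
    _write(auc_table, outdir / "auc_matrix.tsv")
    _write(summary_table, outdir / "metric_summaries.tsv")
    _write(component_table, outdir / "component_report.tsv")
    _write(coverage_table, outdir / "bns_coverage.tsv")
    if not degree_change_table.empty:
        _write(degree_change_table, outdir / "degree_change.tsv")
    if not overlap_table.empty:
        _write(overlap_table, outdir / "subset_overlap.tsv")
    if not distance_table.empty:
        _write(distance_table, outdir / "disease_distance.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(interactome),
        "n_proteins": len(interactome.universe),
        "subsets": {
            name: {
                "n_records": len(rids),
                "n_nodes": networks[name].n_nodes,
                "n_edges": networks[name].n_edges,
            }
            for name, rids in subset_records.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunResult(
        outdir=outdir,
        auc_table=auc_table,
        summary_table=summary_table,
        component_table=component_table,
        coverage_table=coverage_table,
        degree_change_table=degree_change_table,
        overlap_table=overlap_table,
        distance_table=distance_table,
        pathway_table=pathway_df,
        withdrawn_table=withdrawn_df,
        manifest=manifest,
    )
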