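# dtnet

Network-based drug-target analysis over consolidated protein-interaction
data: how data integration, n-ary complex representation, and reliability
filtering change the value of degree and centrality as drug-target
predictors.

## The problem

Drug targets (DTs) — proteins bound by drugs — are repeatedly reported to
sit at high degree and high centrality in protein-interaction networks
(PINs), which makes simple graph metrics tempting features for target
prediction. But every such claim rides on upstream choices: which source
databases are integrated, whether an n-ary ("complex") record is drawn as a
star around a hub (*spoke* model, n−1 edges) or as a clique (*matrix*
model, n(n−1)/2 edges), and which records count as reliable. `dtnet`
implements the full analysis pipeline needed to ask these questions in a
controlled way:

* a record-level data model (a small fixed-column MITAB-like dialect) with
  binary and n-ary records, provenance, confidence scores and a
  predicted-interaction flag;
* **B/N/S classification** — true binary data (B), n-ary complex data (N),
  and spoke-represented n-ary data (S): binary records from the same
  database, publication and n-ary-generating detection method that share a
  protein are collapsed into one S unit;
* spoke/matrix network construction with per-edge record provenance;
* reliability subsets: low-throughput publications (`lpr < 22`, where a
  publication's lpr is the number of distinct pairs it reports), confidence
  scores (`MI-IntAct > 0.6`, `MI-PSICQUIC > 0.7`), predicted-record
  exclusion, and binary-only data;
* node metrics — degree, unnormalised betweenness centrality
  (BC(v) = Σ_{s<t} σ_st(v)/σ_st), closeness centrality (CC(v) = 1/Σ_u d(v,u)
  over reachable u), and *pathway centrality* (number of annotated pathways
  crossing a protein);
* evaluation — hypergeometric over-representation of targets across
  degree-rank bins of ≥ 200 proteins (upper tail P(X ≥ k), raw p < 0.05),
  and ROC curves with trapezoidal AUC, constructed tie-grouped so that
  AUC ≡ the Mann–Whitney statistic U/(P·N);
* a seeded synthetic generator that plants every structure the analysis
  assumes (heavy-tailed backbone, S-groups, HTP/LTP publications,
  score-reliability link, degree-biased target labels with weight ∝
  degree^β, DT-enriched pathways, disease overlap, high-centrality
  withdrawn targets) and returns the ground truth for validation.

## Worked example

```python
from dtnet import GeneratorConfig, RunConfig, run_pipeline

config = RunConfig(
    generator=GeneratorConfig(
        n_proteins=1200, n_drug_targets=120, n_complexes=80,
        n_ltp_pubs=500, n_pathways=60,
    ),
    metrics=("degree", "betweenness", "closeness"),
    roc_labels=("drug_target", "cancer_dt"),
    min_bin_size=100,
    outdir="run1", seed=7,
)
result = run_pipeline(config)
print(result.auc_table[result.auc_table.label == "drug_target"]
      .pivot(index="subset", columns="metric", values="auc").round(4))
```

```
metric       betweenness  closeness  degree
subset
binary_only       0.7030     0.6608  0.7156
full              0.7134     0.6765  0.7307
ltp               0.6677     0.6390  0.6970
mi_intact         0.6239     0.4449  0.6274
mi_psicquic       0.5920     0.4215  0.5907
no_predicted      0.7030     0.6709  0.7127
```

Each row is its own graph: the subset's records are filtered, re-classified
and rebuilt, and the metric is computed within that network. With targets
planted at degree bias β = 1.5, degree and BC are informative but imperfect
predictors (AUC ≈ 0.7), and none of the "more reliable" subsets beats the
full network — the score-filtered subsets (few hundred nodes) drop toward
chance. The same run reports the rest of the study: cancer-restricted
targets are easier to predict (degree AUC 0.9263 on this data), drug
targets lose more edges than non-targets under every filter (rank-sum p in
`degree_change.tsv`), withdrawn-drug targets show far higher betweenness
than other targets (means 41333 vs 2237, p = 1.5e-08 in
`withdrawn_centrality.tsv`), and pathway centrality evaluated over the
whole universe (zero-pathway proteins included) outperforms degree
(`pathway_centrality.tsv`). The same pipeline runs on file inputs
(`interactions=`, `labels=`, `pathways=` in the dialect/TSV/GMT formats)
instead of a generator, and from the shell via `dtnet run --config
run.yaml`; individual stages are exposed as `dtnet generate | classify |
filter | build | metrics | enrich | roc`.

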