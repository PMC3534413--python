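# Methods

## Data model and the interaction dialect

An interaction record is an ordered list of ≥ 2 canonical protein IDs plus
provenance (source database, publication ID, detection method), two
optional confidence scores in [0, 1] (`mi_intact`, `mi_psicquic`, produced
by external scoring services and only *thresholded* here), and a
predicted-interaction flag. Binary records have exactly two interactors;
complex (n-ary) records at least three, with an optional 0-based
`hub_index` naming the bait/hub (defaulting to the first interactor, the
bait-first convention of consolidated indices). Records travel in a fixed
10-column TSV; a missing score is an empty field, a first-class state
distinct from 0.0. Protein identifiers are opaque: any sequence-based
canonicalisation and record deduplication is assumed to have happened
upstream.

## B/N/S classification

Complex records are class N. Binary records whose (source database,
publication, detection method) key uses a method configured as
n-ary-generating, and which share at least one protein with another binary
record under the same key, are collapsed into S-groups (transitively, by
shared proteins); everything else is class B. We require shared-protein
connectivity rather than grouping a whole key blindly: a lone binary
record under an n-ary key has nothing to be a spoke *of*, so it stays B.
An S-group's derived member set is the union of its records' interactors;
its hub is the protein common to all its records if one exists, otherwise
the most frequent member, ties broken lexicographically (the common case —
all spokes share the bait — needs no tie-break; the fallback only covers
pathological groups).

## Networks

Spoke expansion of an n-member unit yields the n−1 hub–member pairs;
matrix expansion all n(n−1)/2 pairs; a binary record yields its single
pair either way. Networks are simple undirected graphs: self-pairs are
dropped (degree counts distinct partners — this avoids the loop-counting
ambiguity between graph toolkits), duplicate pairs merge into one edge
carrying the union of supporting record IDs, and the node set is the set
of edge endpoints, so proteins with only self-interactions vanish. One
deliberate exception: label-restricted subnetworks keep isolated labelled
nodes, so that "average degree of the drug-target subnetwork" is an
average over all drug targets present in the parent network, not only the
ones with a within-group edge.

## Reliability filters

The lpr of a publication is the number of distinct unordered pairs
produced by spoke-expanding every record citing it; a record inherits its
publication's count and an edge supported by several records takes the
minimum. lpr is computed on the **full** interactome before any
sub-setting, so filtering cannot change a publication's throughput class.
All filter inequalities are strict (`lpr < 22`, `mi > 0.6`, `mi > 0.7`),
and a missing score fails a score filter: an unscored record cannot
certify its own reliability, and the interesting regime for score subsets
is aggressive exclusion. The MI-PSICQUIC default is 0.7; 0.8 is an equally
defensible published choice and the threshold is a plain parameter.
Filters compose by intersection. In the pipeline, `binary_only` is applied
against the full interactome's classification; after any filtering the
surviving records are *re-classified* before network building, because
removing records can turn a former S pair into a lone binary.

## Metrics

* degree — incident edges in the simple graph;
* betweenness — unnormalised, each unordered pair counted once, tied
  shortest paths sharing credit fractionally (raw values, as network
  toolkits print them);
* closeness — 1/Σd over the nodes reachable from v. Prose definitions
  often say "mean shortest distance"; the reciprocal-of-sum is what the
  classic igraph routine computes, and since ROC/AUC is rank-invariant the
  1/(n−1) scale difference cannot change any conclusion here. Nodes with
  no reachable peer get closeness 0.
* pathway centrality — the number of annotated pathways containing the
  protein. Two universes are reported: proteins in ≥ 1 pathway, and every
  network protein with absent ones valued 0. The distinction matters: most
  of the signal in the zero-inclusive variant comes from pathway
  *membership* itself, not the count.

Betweenness and closeness are delegated to igraph's C implementations
(needed at the 5000-node synthetic scale); the test suite holds both
against an explicit all-pairs shortest-path enumeration oracle at 1e-9.

Moment summaries report skewness g1 = m3/m2^1.5 and non-excess kurtosis
b2 = m4/m2² with biased moment estimators (the `moments`-package
convention), sample SD with n−1, and NaN for both shape moments at zero
variance. Connected components order by size descending with equal sizes
ordered by smallest contained node ID, making component reports
deterministic. Distances from sources to a target set use multi-source
BFS; sources in the target set are distance 0, sources with no path land
in an explicit unreachable bucket, and sources absent from the network are
reported separately rather than conflated with unreachable.

Rank-sum comparisons (two-sided) use exact enumeration of all rank
assignments for tie-free samples with combined n ≤ 12 — small enough to
enumerate instantly, large enough to cover the worked examples — and the
normal approximation with tie and continuity correction otherwise. Two
identical one-point samples short-circuit to p = 1.

## Binning and ROC

Rank bins grow greedily down the sorted metric: fill to ≥ `min_bin_size`
(default 200), always absorbing whole tie groups (no metric value is ever
split across bins), and merge an undersized final bin into its
predecessor. The bin-growing rule is parameterised because real analyses
differ in how aggressively they pad bins. Over-representation uses the
inclusive upper tail P(X ≥ k) of the hypergeometric; no multiple-testing
correction is applied across bins (raw p < α, α = 0.05 default) — a
correction hook is a natural extension but the exported tables carry raw
p-values so any correction can be applied downstream.

ROC thresholds sweep distinct score values descending with all tied nodes
entering together, one vertex per distinct value, prefixed with (0,0).
This makes the trapezoidal area *identical* to the tie-corrected
Mann–Whitney U/(P·N) — the probability a random positive outranks a random
negative — rather than an approximation of it; per-node stepping under
ties would not have this property.

## The synthetic generator

The generator emulates the structure of a consolidated interactome plus
drug-target annotations, with every feature planted by an explicit knob
(defaults in parentheses):

* preferential-attachment backbone of binary records (5000 proteins, 4
  edges per arriving node) — gives the right-skewed degree distribution
  that real consolidated PINs show; no attempt is made to match any
  particular database's exact moments, which are properties of a data
  release, not of the method;
* complexes (300) with truncated-geometric sizes (p = 0.35 on [3, 20]);
  a fraction (0.3) is emitted as S-groups — hub-spoke binary records
  sharing one dedicated publication, database and n-ary method (a small
  study reporting one complex) — the rest as true n-ary records;
* publications: records are spread by shuffled round-robin over 20 HTP and
  2000 LTP publication IDs (50/50 record split), so HTP papers accumulate
  hundreds of distinct pairs and LTP papers a handful, and the lpr filter
  has a crisp ground truth;
* predicted flags on 15% of backbone records (stamped with a
  predicted-source database);
* MI scores ~ Normal(μ, 0.15) clipped to [0, 1], μ = 0.40 rising by 0.15
  per extra record supporting the pair (capped) — reliability is linked to
  multi-record support; 30% of scores are missing, since real score
  coverage is partial;
* drug targets (300) sampled without replacement with weight degree^β
  (β = 1.5 default; β = 0 is the uniform null). The power form gives one
  interpretable knob; a logistic-in-log-degree alternative would serve
  equally;
* pathways (150, truncated-geometric sizes on [5, 80]) sampled with a
  4× odds multiplier for drug targets — pathway membership is enriched for
  targets, as pathway databases are;
* disease proteins: 1.7 × the target count (the ratio real DT and
  disease-protein lists show), with 35% of targets also disease proteins —
  targets are related to, but not identical with, disease genes;
* withdrawn targets: 10% of targets sampled from the top betweenness
  decile of targets — planting the observed association between high
  centrality and withdrawal so the comparison has signal to find;
* cancer targets: a degree-biased 25% subset of targets, making the
  cancer-restricted prediction task genuinely easier, as observed on real
  annotations.

Weighted sampling without replacement uses Gumbel top-k keys (exact and
vectorised); everything derives from one `numpy` Generator, so a fixed
seed gives byte-identical output files.

What the generator does **not** emulate: literature-driven correlation
between annotation effort and degree (study bias), protein families and
sequence redundancy, database-specific curation styles, true biological
module structure, or drug–drug similarity. Passing recovery tests
therefore shows the *pipeline* is correct and sensitive under the stated
generative assumptions — not that real drug targets follow a degree^β law.

## Validation and problem sizes

The heavy recovery checks run the standing synthetic conditions — 5000
proteins, 300 planted targets, 20 seeds per β ∈ {0, 0.5, 1, 1.5} — chosen
as the smallest scale at which the binomial noise on a 20-seed mean AUC
(≈ ±0.007) is comfortably inside the ±0.02 calibration band asserted at
β = 0. B/N/S recovery runs 20 seeds at 1000 proteins (recovery is exact at
any size); lpr-filter recovery 5 seeds at 2000 proteins; the
representation, edge-removal and withdrawn-target comparisons ride on the
β = 1.5 datasets. Oracle equivalences use 200 random score/label instances
(n ≤ 100), 50 random graphs (n ≤ 25), and every hypergeometric case with
N ≤ 12.

At β = 0 the fraction of significant bins is tested one-sidedly from
above: the hypergeometric test is discrete and conservative, so observed
fractions *below* α are expected behaviour, not miscalibration.

## Known limitations

* The lpr definition (distinct spoke pairs per publication, minimised over
  supporting publications) follows the consolidated-index convention; other
  bibliometric variants exist.
* S-group detection depends entirely on the configured n-ary method list;
  an incomplete list silently leaves S data in B.
* Closeness on disconnected graphs is per-component 1/Σd; values are not
  comparable across components of different sizes (ROC use is unaffected,
  rankings within the giant component dominate).
* The pipeline evaluates each subset's metrics in the subset's own
  network. Restricting full-network metrics to subset nodes is a different
  question and is deliberately not what the AUC matrix reports.
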