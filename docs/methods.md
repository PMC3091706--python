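# Methods

This note records the model assumptions, parameter conventions and design
choices behind `coexnet`, in the order the pipeline runs.

## Synthetic data: what the generator emulates

`simulate_datasets` emulates the statistical setting of a multi-cohort
co-expression study: several independent expression datasets (possibly
with different sample counts) that share a set of co-regulated gene
modules, plus modules private to single datasets, on a background of
unco-regulated genes. Each module in each dataset is driven by one Gaussian
latent factor `f ~ N(0,1)` per sample:

    x_g = sqrt(rho/(1-rho)) * sigma * f + sigma * eps_g

with i.i.d. `eps_g ~ N(0,1)` and `sigma = noise_sd` (default 1, a
dimensionless log-intensity scale). Two genes sharing a factor then have
expected Pearson correlation exactly `rho = within_module_corr`
(default 0.85, high enough that module edges comfortably clear the
τ = 0.70 edge threshold at ~30 samples while background pairs almost never
do). Background genes are i.i.d. `N(0, sigma²)`, which makes the false-edge
rate analytically checkable from the null PCC distribution (for n = 30
samples, P(|PCC| ≥ 0.70) ≈ 10⁻⁵ per pair). Shared modules reuse the same
member genes in every dataset but draw independent factor realizations per
dataset: the *correlation structure* is conserved, the expression values
are not — matching the cross-platform setting where only co-expression
recurs. Default study conditions are three datasets of 30 samples and five
shared 20-gene modules among 1000 genes.

What the generator does **not** emulate: probe-level intensity
distributions, normalization artifacts, batch effects, heavy-tailed or
count-like expression, correlated background (e.g. housekeeping programs),
or negative within-module correlations. Passing tests therefore demonstrate
that the pipeline recovers block-structured linear co-expression under
Gaussian noise — the structural claim the method rests on — not that any
particular biological dataset would yield the same networks.

All randomness flows from explicit `numpy.random.Generator` streams seeded
from a single integer; replicates and datasets use spawned substreams so
results are reproducible and order-independent.

## Preprocessing

Probe-level tables are cleaned before network construction. "Very low
expression" is quantified as a configurable mean-intensity cutoff, by
default the 20th percentile of per-probe means — a quantile rather than an
absolute number because log-intensity scales differ across platforms.
Probe-to-gene collapse keeps, per gene, the probe with the highest mean
intensity across samples; exact ties go to the lexicographically smallest
probe id, making the collapse deterministic and independent of input row
order. Mean (not median or maximum) was chosen as the intensity summary:
it matches the filtering statistic and is stable for the small sample
counts typical of these designs.

## Network construction

Edges require PCC ≥ τ with τ = 0.70 by default. Two conventions are fixed
deliberately:

- **Positive-only thresholding.** The default edge rule ignores negative
  correlations; an `use_absolute_pcc` flag switches to |PCC| ≥ τ for users
  who want anti-correlated pairs.
- **Closed threshold (≥, not >).** Ties at exactly τ are included, so a
  network quoted "at PCC = 0.70" is reproducible from the edge rule alone.

Zero-variance genes are excluded from the correlation matrix with a logged
warning instead of propagating NaNs. Isolated nodes stay in the node set
(so the gene universe is preserved for consensus and precision
computations) but are excluded from "genes in the network" counts; both
counts are exposed.

The scale-free diagnostic is the classic least-squares fit of
log10(node count) against log10(degree) over occupied degree bins. It is a
rough heuristic, not a rigorous power-law test; it is used only
directionally (heavy-tailed growth models fit markedly better than
Erdős–Rényi graphs of the same size).

Network *precision* is the fraction of (non-isolated) network genes
carrying at least one annotation term — a node-level specificity proxy that
is deliberately independent of edge structure.

## Consensus

A consensus edge must appear, as an unordered gene pair, in **every** input
network; weights are ignored for identity. The Conserved network's gene set
is defined as the endpoints of conserved edges, not the intersection of
node sets — consensus membership follows surviving links, and a separate
node-intersection count is reported for users who want the other
convention. Pairwise gene/edge overlaps are reported for every dataset
pair.

## Null model

Randomization uses Maslov–Sneppen double-edge swaps: pick two edges
(a,b), (c,d), propose (a,d), (c,b), accept only if the graph stays simple.
"4 × |E| rewiring steps" is interpreted as **attempted** swaps (rejected
attempts count), the standard convention; the attempt and acceptance counts
are recorded on the rewired graph. Graphs with no legal swap (stars,
triangles) are returned unchanged with a notice. Per replicate, each input
network is rewired independently from a spawned substream; the consensus
gene count of the rewired networks forms the null distribution, summarized
by its mean and sample (n−1) standard deviation, and the observed count is
reported as z = (obs − mean)/sd. When the null is degenerate (sd = 0, e.g.
unswappable inputs) z is reported as undefined alongside the raw
distribution. The default of 200 replicates is a distributional convention;
tests and the acceptance script use 50, which is ample for a z-score that
sits many SDs from the null.

## Topology

Betweenness is unnormalized shortest-path betweenness over unordered node
pairs, endpoints excluded, with fractional credit across tied shortest
paths — the convention under which published per-gene values reach the
10⁴–10⁵ range on ~2000-node networks. Characteristic path length averages
shortest-path distances over *connected* pairs only; disconnected pairs are
excluded and counted, never assigned an arbitrary distance. Some network
studies label this same average-distance quantity the network "diameter";
the package exposes it under both names (`characteristic_path_length`,
`paper_diameter`) and additionally reports the conventional
max-eccentricity diameter, computed per component.

The core is the induced subgraph of nodes with log(betweenness) above a
threshold (default 6), hubs additionally exceed a degree threshold
(default 15). Natural log is the default base: on ~2000-node networks
typical central-gene betweenness values (10⁴–10⁵) give ln values of 9–12,
so a threshold of 6 selects roughly the top half — whereas log10 would
select nothing. The base is configurable because the absolute betweenness
scale depends on the pair-counting convention. Nodes with betweenness 0
never pass any log threshold.

Hub removal freezes the target ranking at the intact graph's degrees
(descending, ties by gene id) — modelling the removal of a pre-identified
hub list — with an adaptive re-ranking mode behind a flag. Metrics
(average betweenness, CPL, component count) are recorded for the intact
graph and after every `recompute_metrics_every` removals; CPL is computed
over remaining connected pairs and reported as NaN when none remain.

## MCL

The flow matrix is the adjacency with self-loops of weight 1 added
(standard practice; prevents period-2 oscillation on bipartite-like
structures), column-normalized. Each iteration applies expansion (matrix
power, default 2) then inflation (entrywise power, default 1.3,
renormalize); entries below `prune_threshold` (default 1e-5) are zeroed
with column renormalization to keep dense intermediates tractable —
exactness on toy graphs is verified with pruning disabled. Convergence is
declared when the max entrywise change drops below 1e-8. Clusters are read
off the limit matrix: attractors (nodes retaining diagonal flow) are
grouped into attractor systems by overlapping row support, and every node
joins the system capturing most of its column flow; overlap (rare) resolves
to the strongest attractor, ties to the lowest-indexed cluster, so the
output is always a deterministic partition. Clustering runs on the
unweighted 0/1 adjacency by default, matching the undirected unweighted
network definition; a PCC-weighted mode exists but is not used in the
default pipeline. Singleton clusters are counted as clusters, with the
singleton count reported separately; the cluster-size filter (default
min 10 genes) is applied before enrichment.

## Enrichment

For cluster C and term T over background B (default: the analyzed
network's genes; a gene-universe mode is available), the 2×2 table is
a = |C∩T|, b = |C\T|, c = |T\C∩B|, d = |B\(C∪T)| and the score is
ln[(a·d)/(b·c)]. The natural-log base and the Haldane–Anscombe ε = 0.5
zero-cell correction (applied only when a cell is zero) are package
conventions, documented rather than inherited. A term that covers the
entire background is scored 0 (both proportions are 1, so there is no
enrichment by definition; the ε-corrected formula would otherwise return a
spurious cluster-size artifact). GO-BP-style collections drop terms with
≥ 1500 genes to avoid uninformative broad categories; KEGG-style
collections are never size-filtered. Ranking is by log-odds magnitude
alone; optional Fisher exact p-values with Benjamini–Hochberg adjustment
are provided behind a flag as a modern convenience, outside the default
analysis.

## Problem sizes and numerical choices

The test suite and acceptance script run the full method at 1000 genes ×
3 datasets × 30 samples with five 20-gene planted modules (the default
study conditions), 50 null replicates, 20-seed Monte-Carlo checks, and
500-node preferential-attachment fixtures for the robustness contrast —
sizes at which every distributional claim the package makes is comfortably
resolved. Exact-agreement checks (correlation vs. the two-pass Σ formula at
1e-12; graph metrics vs. exhaustive path-enumeration oracles on ≤ 12-node
graphs) run on small instances where enumeration is feasible.

## Known limitations

- Pearson correlation only (no Spearman/mutual-information similarity, no
  WGCNA-style soft thresholding).
- Hard consensus (all datasets) by design; a "k of n" soft consensus would
  require a different null.
- Dense MCL: memory is O(n²), appropriate up to a few thousand nodes —
  the scale consensus networks reach after intersection, not the scale of
  raw single-dataset networks.
- The log-log degree fit is a diagnostic, not a maximum-likelihood
  power-law estimate.
- Enrichment ignores the annotation DAG (no ancestor propagation) and, by
  default, multiple testing.
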