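# Methods

`platyconn` implements the analysis chain used to derive and interrogate a
whole-body synaptic connectome of a segmented larva from CATMAID-style
reconstructions, together with a synthetic data generator that makes every
stage testable without access to an electron-microscopy dataset.

## Data model

A dataset is three tables. **Skeletons** are rooted trees of 3D nodes in
nanometres, one per cell or per unattached *fragment* (a traced piece with
no soma). Complete skeletons are rooted on the soma and the root node
carries a `soma` tag. **Connectors** are monadic chemical synapses: one
presynaptic skeleton node onto one postsynaptic skeleton node; there are no
gap junctions or polyadic synapses in the model. **Cell annotations** carry
class (`sensory`, `interneuron`, `motoneuron`, `effector`,
`other_non_neuronal`, `fragment`), a cell-type label, the soma body region
(head, segments 0–3, pygidium) and body side. Body-region and side
membership come exclusively from annotations, never from coordinates, so no
axis convention is imposed.

Interchange is one SWC file per skeleton (type column: 1 = soma,
0 = undefined; extra node tags stored in `# tag` header comments so
standard readers ignore them) plus TSV connector/annotation tables.
Serialisation is deterministic (sorted ids, `repr` floats), making the
write→read round-trip an exact identity and outputs byte-stable.

## Connectome derivation

`build_connectome` applies three steps in a fixed order:

1. every synapse has weight one and parallel synapses between the same
   ordered cell pair are summed into a single weighted edge;
2. every cell whose total incident synapse count (in + out) is below
   `min_synapses` (default 3) is removed in a **single pass** — counts are
   taken on the aggregated graph before any removal, with no cascade (an
   iterative, k-core-like variant is available behind `iterative=True` but
   off by default);
3. the graph is restricted to its largest **weakly** connected component
   (ties broken by edge count, then lexicographically smallest member
   name). A feed-forward sensory→effector graph cannot be strongly
   connected, so weak connectivity is the meaningful notion.

Fragments participate as ordinary nodes. Graph metadata records the counts
removed by each step. Density is the directed simple-graph density
e / (n·(n−1)).

`group_by_type` collapses same-type cells into one node, summing synapse
counts; within-type synapses become self-loops; untyped cells and fragments
are excluded and counted. The square-root of the summed weight is attached
as `display_weight` for plotting only — every analysis uses raw counts.

## Network analysis

* **Modules** — Leiden on the directed, synapse-weighted graph with the
  RB-configuration (modularity) objective via `leidenalg`. The resolution
  parameter controls granularity and materially changes the module count,
  so a sweep helper is provided; default resolution 1.0. Runs are
  deterministic under a fixed seed.
* **Centralities** — weighted degree (summed in+out synapse counts),
  PageRank (damping 0.85, weighted out-edges, uniform teleport for dangling
  nodes, solver tolerance 1e−12), betweenness on the *unweighted* directed
  graph (synapse counts are affinities, not distances — treating them as
  distances would invert their meaning; an inverse-weight option could be
  added but is deliberately not the default), and HITS authority on the
  weighted adjacency. Ties share min-rank.
* **Roles** — sources (only outgoing edges; in the larva, mostly sensory
  neurons), sinks (only incoming; mostly effectors), internal, isolated.
* **Flow tables** — edges aggregated by node category with a direction
  flag; connections below 11 synapses (i.e. not ">10") are dropped by
  default, matching the display convention of grouped flow diagrams.
* **Module mixing** — per-module within/between synapse weight; the
  within-fraction of a planted or detected module should exceed the
  between share in a genuinely modular graph.

## Left-right stereotypy

Cell types with exactly one left and one right member form homolog pairs;
midline and unbalanced types are excluded (with the reason recorded) rather
than averaged. The side matrices index paired types on both axes: entry
[T1, T2] of the left matrix sums synapses from the *left* member of T1 onto
members of T2 on either side; the right matrix mirrors this. Correlation is
Pearson on the raw flattened counts with zeros retained — the most
reproducible reading in the absence of a stated transform — with a sqrt
variant behind a flag. Identical matrices short-circuit to exactly 1.0 so
that a perfect mirror is exact rather than 1 − ε in floating point.
Morphological stereotypy correlates the Sholl profiles of the two homolog
skeletons on a shared radius grid extending to the larger extent.

## Paths and segments

Sensory neurons are classified by BFS hop count (number of edges) to the
nearest effector on the directed graph: `sensory-motor` = a direct synapse
onto an effector (1 hop), `premotor` = a direct synapse onto a motoneuron,
`indirect` = 2+ hops, `no-path` = unreachable. Labels are multi-label — a
sensory-motor cell is usually also premotor — matching how such cells are
tabulated. The classifier runs on the cell-level graph or a grouped
type-level graph; both levels are exposed because published path censuses
mix them.

The segment matrix sums synapses between soma body regions (optionally
stratified by class × region); the head-trunk census ranks individual
cells by cross-region output with per-target-class splits. The census
margins equal the segment-matrix head row/column by construction, and the
two are computed by independent code paths as an internal cross-check.

## Morphometry

* **Cable length** (µm) is measured on *trimmed, unsmoothed* skeletons:
  terminal twigs (tip up to the first branch point) shorter than 2 µm are
  pruned in a single pass over the original tree, then Euclidean edge
  lengths are summed. The threshold is configurable; 2 µm is the sensible
  scale for removing tracing stubs — a millimetre-scale threshold would
  delete entire cells, whose largest exemplars reach only 1.2–1.7 mm of
  total cable.
* **Smoothing** (sigma 6000 nm) is a Gaussian-weighted moving average
  along each unbranched stretch, applied to *chord residuals* with the
  stretch endpoints (root, branch points, tips) anchored. Smoothing the
  residuals rather than the raw coordinates makes a straight stretch an
  exact fixed point (truncated Gaussian windows would otherwise slide
  end-adjacent nodes along the line). Topology, radii and tags are
  untouched; smoothing feeds rendering and Sholl, never synapse positions.
* **Sholl** runs on smoothed, *untrimmed* skeletons: for radii at every
  multiple of the step, an edge crosses the sphere when the endpoint
  nearer the root lies within the radius (inclusive) and the farther one
  beyond it. As the radius approaches zero the crossing count equals the
  root degree.
* **Radial synapse density** histograms the *Euclidean* distance from the
  soma node to each synapse node in fixed 1000 nm bins (the stated radius
  is read as the bin width); distances are radial, not geodesic along the
  arbour. Class-level means average per-cell profiles on a shared
  zero-padded grid. Fragments have no soma and are rejected.
* **Polarity** counts pre- and postsynaptic sites per cell from the
  connector table; the presynaptic fraction separates classes (sensory
  high, effectors zero). Because synapses are monadic, total pre = total
  post = connector count on any dataset — asserted throughout the tests.

## Synthetic generator

The generator emulates the *structure* of a segmented larval dataset, not
any real animal's counts. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| body regions | 6 (head, sg0–3, pygidium) | the larval body plan |
| types per class per region | SN 2, IN 2, MN 1, effector 1 | small but class-complete |
| cells per type | 2 (one left, one right) | most types are homolog pairs |
| fragment_fraction | 0.15 | fragments are ~17 % of connectome nodes |
| n_modules / p_within / p_between | 3 / 0.26 / 0.03 | planted, recoverable modules |
| class_order_bias | 0.9 | strong SN→IN→MN→effector feed-forward flow |
| mirror_noise ε | 0.1 | yields left-right correlation ≈ 0.9 |
| synapses per edge | 1 + NegBin(r=2, mean 3) | overdispersed counts; per-neuron medians ≈ 8 pre / 6 post |

Skeletons are simple arbors (soma + main neurite + Poisson-count twigs);
right homologs are exact mirror images (x → −x) of their left partners, so
morphological stereotypy is exact at ε = 0. Wiring is planted at the
type level: types are assigned round-robin to modules, type pairs connect
with p_within inside and p_between across modules, backward class pairs
are thinned by (1 − class_order_bias), and effectors never send. Each
left-side type edge is mirrored with the same synapse count except an
ε-fraction whose right-side target and count are resampled — so the
left/right matrices are identical at ε = 0 and decorrelate as ε → 1.
Fragments attach sparsely with random partners. All stages derive child
generators from `SeedSequence([seed, stage])`, so each stage is
independently reproducible; the generator also records its own running
cable-length sum per skeleton as an oracle independent of the morphometry
code.

What the generator does **not** emulate: realistic neurite geometry,
electrotonic structure, per-type connection specificity beyond modules,
developmental gradients, or reconstruction artefacts other than soma-less
fragments. Tests passing on synthetic data therefore certify the
*algorithms* (filtering rules, aggregation, recovery of planted structure),
not biological conclusions about any real dataset.

## Problem sizes and numerical choices

The default test and acceptance runs use the generator's standard body plan
(~83 cells, ~500–900 synapses), 20-seed repetitions for the stochastic
recovery suites, 100 random datasets for graph-build equivalence and 200
for path-classification oracle checks — sizes chosen so the whole suite
exercises every code path in seconds while keeping Monte-Carlo standard
errors well inside the asserted margins. Ties in centrality ranks share the
min rank; correlation of constant matrices or profiles raises rather than
returning NaN; density requires ≥2 nodes; an empty synapse table or a graph
emptied by filtering is an error carrying the removal counts.

## Known limitations

* The <3-synapse rule is single-pass by design; after component selection
  some nodes can retain fewer than 3 in-graph synapses (their other
  synapses having been removed with filtered neighbours). This mirrors the
  stated derivation order rather than enforcing a k-core.
* Left-right matrices exclude midline and unbalanced types entirely;
  asymmetric circuits are invisible to the stereotypy score.
* Sholl crossing counts use Euclidean distance to the root, so strongly
  curved neurites that re-enter a sphere are counted once per edge
  straddle, which is the standard convention but not a geodesic measure.
* The CLI covers simulate/validate/report; module detection, stereotypy
  and path censuses are library-level APIs.
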