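# platyconn

Whole-body connectome analysis for segmented larval nervous systems.

Serial-EM reconstructions of small animals yield three things: neuron
skeletons (rooted trees of 3D points), a table of chemical synapses
(monadic: one presynaptic skeleton node onto one postsynaptic node), and
per-cell annotations (class, cell type, body segment, body side).
`platyconn` turns those into the synapse-weighted directed connectome
graph and the standard whole-body analyses built on it:

* **Graph derivation** — synapses aggregated into weighted edges, cells
  with fewer than 3 total incident synapses removed in a single pass,
  restriction to the largest weakly connected component; grouped
  cell-type graph with summed weights.
* **Network analysis** — Leiden community detection (resolution sweep),
  weighted degree / PageRank / betweenness / HITS-authority rankings,
  source-sink classification, thresholded category flow tables,
  within- vs between-module synapse fractions.
* **Left-right stereotypy** — homolog pairing per cell type, side-split
  type-level synapse matrices and their Pearson correlation, Sholl-profile
  similarity of homolog skeletons.
* **Pathways and segments** — BFS classification of sensory neurons by hop
  distance to effectors (sensory-motor, premotor, 2+ hops, no path),
  6×6 body-region synapse matrices, head↔trunk censuses.
* **Morphometry** — cable length with 2 µm twig pruning, Gaussian skeleton
  smoothing (σ = 6 µm), Sholl profiles, radial synapse density (1 µm
  bins), pre/post polarity tables.
* **Synthetic larva generator** — segmented body plan, mirror-image
  left/right homolog skeletons, planted connectivity modules, feed-forward
  class bias, tunable mirror noise, soma-less fragments — with full ground
  truth, so every stage above is testable without an EM dataset.

For a connectome graph G = (V, E) with edge weights w(u→v) = summed
synapse counts, the package reports density e/(n(n−1)), modularity-based
Leiden partitions, PageRank with damping α = 0.85 on weighted out-edges,
and the left-right correlation r = corr(Lᵢⱼ, Rᵢⱼ) over type pairs, where
Lᵢⱼ counts synapses from the left member of type i onto type j.

## Worked example

```python
from platyconn import graphs, network, stereotypy, synthetic

# a synthetic segmented larva: 6 body regions, left/right homolog pairs,
# 3 planted modules, mirror noise 0.1
ds, truth = synthetic.generate_dataset(seed=1)
print(len(ds.cells), "cells,", len(ds.connectors), "synapses")

g = graphs.build_connectome(ds, min_synapses=3)
print(g.number_of_nodes(), "nodes,", g.number_of_edges(),
      "edges, density", round(graphs.graph_density(g), 4))

part = network.leiden_modules(g, resolution=1.0, seed=0)
print(part.n_modules, "modules, modularity", round(part.quality, 3))

m = stereotypy.side_matrices(graphs.synapse_graph(ds), ds.cells)
print("left-right correlation", round(stereotypy.lr_correlation(m), 3))
```

prints

```
83 cells, 620 synapses
39 nodes, 100 edges, density 0.0675
6 modules, modularity 0.509
left-right correlation 0.892
```

83 cells (72 typed cells in 36 left/right pairs plus 11 fragments) carry
620 synapses; the <3-synapse filter and component rule keep 39 cells. The
left/right type-level matrices correlate at 0.89 — high but imperfect
stereotypy, as expected with 10 % mirror noise.

A thin CLI wraps the same pipeline:

```sh
platyconn simulate --out-dir sim --seed 3      # SWC + TSV + ground_truth.json
platyconn validate sim                          # invariant check
platyconn report sim --out-dir rep              # report.json + connectome.graphml
```

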