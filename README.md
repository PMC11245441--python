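# mlbundle

Multi-layer bundling of correlation networks: multi-resolution spectral
clustering with recursive intersection, bridge-set detection, and
reconstruction of the network of clusters.

## The problem

Spectral clustering of a correlation network asks the user to pick a
number of clusters. The eigengap heuristic offers candidates — every large
gap in the ascending eigenvalues of the normalized graph Laplacian flags a
natural cluster count — but different choices (*clustering regimes*) split
the features in different, sometimes orthogonal, ways. For gene
co-expression, metabolite or any feature-correlation data, committing to
one regime throws away the information held in the others.

Multi-layer bundling keeps all of the prominent regimes. From a
sample-by-feature matrix **S** (m × n) it builds the affinity
**A** = |**R**| (absolute Pearson correlations, zero diagonal), the
normalized Laplacian **Q̂** = **D**⁻¹ᐟ² (**D** − **A**) **D**⁻¹ᐟ², and
ranks eigenvalue indices κ₁, κ₂, … by descending eigengap
δᵢ = λᵢ₊₁ − λᵢ. Regime *i* clusters the features into κᵢ groups using the
first κᵢ eigenvectors (QR-pivot label assignment). A **layer-ℓ bundle** is
a maximal set of features sharing a cluster in every one of regimes 1…ℓ:

B_ℓ = { β = ∩ᵢ₌₁..ℓ ξⁱⱼᵢ ≠ ∅ }

Layers refine — once two features separate they never rejoin — giving a
global-to-local hierarchy without any tunable parameter beyond the depth.
On top of the layers the package computes:

* **Bridge factors** γₓ = ∏_{y∈Nₓ} |y|/|x| (0 if a group has fewer than
  two neighbours): large exactly when a *small* bundle joins several much
  larger ones — the signature of a transitional, information-carrying
  bridge set.
* **Bundle networks**: the bundle affinity matrix
  **H**ᵏ₍ₓ,ᵧ₎ = Σ_{i∈βₓ, j∈βᵧ} **A**ᵢⱼ / (|βₓ||βᵧ|) and the bundle
  co-cluster matrix **L**ᵏ, which accumulates over regimes 1…r the
  fraction of each shared cluster occupied by two bundles — the history of
  co-clustering that a single clustering discards. Either matrix (or their
  min-max-normalized sum, "LH") is turned into a graph over bundles: each
  row contributes an edge to its largest off-diagonal entry, then leftover
  entries are scanned in descending order and added only when they merge
  connected components. Against synthetic data the result is scored by the
  Jaccard index of its edge set with the target network obtained by
  projecting bundles onto the generating structural network.

The package ships the matching synthetic-data generator (branching-process
structural networks with signed edges and value propagation), so every
stage is testable with a known ground truth.

## Worked example

```python
import mlbundle as mb

cfg = mb.SynthConfig(phi=0.8, n=500, m=400, sigma=0.2,
                     n_extra_edges=10, seed=1)
rng = cfg.rng()
net = mb.assign_edge_polarities(mb.grow_structural_network(cfg, rng), rng)
S = mb.synthesize_feature_matrix(net, cfg, rng)

model = mb.MultiLayerBundling(n_layers=5, n_regimes=12).fit(S)
print(model.spectrum_.regime_order[:5].tolist())   # [1, 2, 3, 4, 5]
print([bl.n_bundles for bl in model.layers_])      # [1, 2, 5, 11, 14]
```

The five most prominent eigengaps here suggest 1, 2, 3, 4 and 5 clusters;
intersecting those regimes yields 1, 2, 5, 11 and 14 bundles at layers 1–5.
Reconstructing the layer-5 bundle network and scoring it against the
ground-truth projection:

```python
layer = model.bundle_layer(5)
H = mb.bundle_affinity_matrix(model.affinity_, layer)
L = mb.bundle_cocluster_matrix(model.regimes_, layer)
target = mb.target_bundle_network(layer, net)
for tag, M in (("H", H), ("L", L), ("LH", mb.combine_scores(H, L))):
    rec = mb.score_matrix_to_network(M, tag)
    print(tag, rec.n_edges, round(mb.jaccard_index(rec, target), 3))
# H 13 0.478 / L 13 0.478 / LH 13 0.478
```

Each reconstruction recovers 11 of the 21 target edges with 2 false
positives (Jaccard 0.478; on this easy, hub-dominated realization the
three methods agree — averaged over replicates LH wins, see below). The
strongest bridge sets are small bundles wedged between large neighbours:

```python
rep = mb.bridge_factors(layer, mb.project_group_adjacency(layer, net))
rep.sort_values("log10_gamma", ascending=False).head(3)
#  group_id  size  n_neighbors   gamma
#        13     1            2  4550.0
#        11     1            2  1881.0
#        10     2            2  1237.5
```

A singleton bundle with two large neighbours (γ = 4550) is the clearest
bridge. The same pipeline is available from the shell:

```bash
mlb all --phi 0.8 --n 500 --m 400 --sigma 0.2 --seed 1 -k 5 -r 12 --outdir out/
# H: jaccard=0.478, L: jaccard=0.478, LH: jaccard=0.478
```

writing edge lists, feature matrices, bundle assignments, size profiles,
score matrices, networks and evaluation tables as `#`-commented TSV.
Subcommands `simulate`, `bundle`, `bridges`, `network` and `evaluate` run
the stages separately; `mlb --help` lists the flags.

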