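# Methods

## Model and procedure

Multi-layer bundling treats a sample-by-feature matrix **S** (m × n) as
noisy observations over an unknown feature-interaction network and asks
for a multi-resolution grouping of the features. The pipeline:

1. **Affinity.** R = Pearson correlation between feature columns;
   A = |R| with the diagonal set to 0. Zeroing the diagonal before
   building the degree matrix (Dᵢᵢ = Σ_{j≠i} Aᵢⱼ) is what makes the
   smallest Laplacian eigenvalue exactly 0; correlations are clipped to
   [−1, 1] against floating-point spill.
2. **Spectrum.** Q = D − A, Q̂ = D⁻¹ᐟ²QD⁻¹ᐟ² (symmetrized after the
   product to keep the eigensolver on the symmetric path). Eigenvalues
   ascend; eigengaps δᵢ = λᵢ₊₁ − λᵢ are ranked descending with ties
   resolved toward the smaller index, giving cluster counts κ₁, κ₂, …
3. **Regimes.** Regime i partitions features into κᵢ clusters by
   QR-pivot label assignment on the first κᵢ eigenvectors of Q̂:
   column-pivoted QR of the transposed embedding selects κᵢ anchor rows,
   the SVD of the anchor block gives an orthogonal rotation, and each
   feature takes the arg-max absolute entry of its rotated row. The
   assignment is deterministic and insensitive to eigenvector sign flips.
   The eigenvector rows are used unscaled (no D⁻¹ᐟ² or row-norm
   rescaling); with κᵢ = 1 all features share one label.
4. **Bundles.** Layer ℓ is the partition into equivalence classes of the
   per-feature tuple (regime-1 label, …, regime-ℓ label) — identical to
   enumerating nonempty cluster intersections but O(nℓ). Bundle ids are
   canonical: descending size, ties to the smallest member id. This makes
   every downstream artifact invariant to arbitrary cluster label values.
5. **Bridge factors.** For a partition projected onto a neighbour graph,
   γₓ = ∏_{y∈Nₓ}|y|/|x| if |Nₓ| > 1 else 0. The product is accumulated in
   log₁₀ space (singleton bundles between several hundred-node neighbours
   overflow doubles otherwise) and both γ and log₁₀γ are reported. The
   neighbour graph is pluggable: projection of a known structural network
   (the synthetic validation route) or a reconstructed bundle network for
   data with no ground truth — the latter is an extension, not a validated
   equivalence.
6. **Bundle networks.** Hᵏ averages affinities across bundle pairs
   (indicator-matrix product, exact mean over |βₓ||βᵧ| entries). Lᵏ sums,
   over regimes ℓ ≤ k, (|βₓ|+|βᵧ|)/|ξ| when one cluster ξ holds both
   bundles, and over regimes k < ℓ ≤ r, (|βₓ∩ξ|+|βᵧ∩ξ|)/|ξ| for every
   cluster ξ holding members of both. Because layer k refines regimes
   1…k, the "shared cluster" at ℓ ≤ k is unique when it exists, so the
   first term reduces to a same-cluster indicator. L's diagonal is
   defined as 0 and never used. Edge selection: (1) every row adds an
   edge to its largest off-diagonal entry, ties to the smallest column —
   with that tie rule the step-1 edge set is provably acyclic, hence at
   most N−1 edges; (2) remaining entries are scanned once in descending
   order (ties lexicographic by (row, col)) and added only when they
   merge components, stopping at one component. LH uses the sum of the
   two matrices after min-max scaling of each matrix's off-diagonal
   entries to [0, 1]; a constant matrix scales to zeros. Jaccard of two
   empty edge sets is defined as 1 (identical networks).

## Synthetic-data generator

The generator is the package's study harness, not a fixture. A tree grows
from one node: the current node (FIFO over creation order) receives
children while uniform draws stay below the branching parameter φ, growth
truncates the instant n nodes exist, and if the queue empties early a
random existing node is re-enqueued (termination guarantee; the local
branching law is unchanged). Ten extra edges between random non-adjacent
pairs create cycles; a uniformly random half of the edges (⌊E/2⌋ when odd)
is labelled +1, the rest −1. Values propagate breadth-first from a random
seed node: seed ~ N(0, σ), every later node ~ N(μ, σ) with μ the mean of
polarity-signed values over already-assigned neighbours (0 if none —
unreachable on a connected graph). m replicates stack into S.

Defaults are the study conditions: φ = 0.8, n = 500, m = 400, σ = 0.2,
10 extra edges. The generator emulates signed, locally propagated
correlations on a known topology; it does **not** emulate heavy-tailed
expression distributions, missing data, batch effects or heteroscedastic
noise, so passing tests demonstrate method correctness and behaviour on
networks of this family, not performance on any real assay.

A closed form worth noting: for a single "+" edge, the two features'
population correlation is 1/√2 ≈ 0.707 *independent of σ* (seed and
propagation noise contribute equal variance). Longer paths attenuate
correlation geometrically, which is what makes bundles localize on the
network.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| φ | 0.8 | branching probability; high → hub-dominated networks |
| σ | 0.2 | propagation noise s.d. (value units) |
| n, m | 500, 400 | features, samples |
| k (`n_layers`) | 5 | bundle depth; the method's single real knob |
| r (`n_regimes`) | 12 | regime horizon feeding L |
| size thresholds | 1, 5, 50 | bundle-size profile counts |

The stopping layer is reported, never auto-applied: the size-profile
table flags the first layer whose counts at every threshold equal the
previous layer's (a "plateau"), mirroring the visual rule of examining
where the size distribution stabilizes. k = 5 and r = 12 are the
reference configuration for network reconstruction.

## Numerical choices

* Dense symmetric eigensolver (`scipy.linalg.eigh`); n ≈ 500 in scope, no
  sparse path.
* "Zero" eigenvalue tolerance: 1e−8 absolute.
* Eigengap ties → smaller index; row-max ties → smaller column; step-2
  ties → lexicographic (row, col); "largest γ" ties → smaller group id.
* Eigengenes: features standardized (ddof = 1) before the SVD; the score
  sign is fixed to correlate nonnegatively with the bundle's mean
  standardized feature. Zero-variance features are an error, as is any
  zero-variance column at the affinity step (named in the message).
* All randomness flows through one `numpy.random.Generator`; fixed seed ⇒
  bit-identical networks, data, partitions and reconstructions.

## Design choices where the design was open

* Seed-node values are drawn from N(0, σ), the same law as unanchored
  nodes; traversal is breadth-first with neighbours in ascending id.
  Other orders satisfy the same local law; breadth-first is fixed for
  reproducibility.
* The estimator shape is scikit-learn's: `MultiLayerBundling(n_layers,
  n_regimes, affinity).fit(X)` with `labels_`, `layers_`, `regimes_`,
  `spectrum_` fitted attributes, composing with sklearn tooling;
  module-level functions expose each stage for scripting.
* Bridge reporting for partitions without a known structural network uses
  the reconstructed bundle network as the neighbour source and is flagged
  as such in reports.
* The normalization before adding H and L (min-max over off-diagonals) is
  one of several defensible choices; rankings, not magnitudes, drive edge
  selection, so any strictly monotone rescaling of each matrix yields the
  same step-1 edges.

## Problem sizes used in the test suite

Partition/refinement and bridging comparisons run on 20 replicates at
n = 200, m = 200 (φ ∈ {0.5, 0.8}); the reconstruction comparison runs the
full reference configuration (φ = 0.6, n = 500, m = 400, k = 5, r = 12,
20 replicates); planted-bridge recovery uses two 50-node φ = 0.8
communities joined by one cut node, 20 seeds. Oracle tests cover all
instances with n ≤ 30 against exhaustive enumeration at 1e−12.

## Known limitations

* Only the |Pearson| affinity is built in; alternative affinities enter
  via the `precomputed` path.
* The co-cluster matrix assumes the layer was formed from the same regime
  stack it is scored against (checked, not inferred).
* Bundle counts on any single realization are seed-dependent; only
  distributional statements (refinement laws, mean Jaccard orderings,
  bridge-recovery rates) are stable, and those are what the tests assert.
* No significance testing of reconstructed edges, and no alternative
  reconstruction rules (thresholding, spanning trees).
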