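# Methods

## Model

`comanifold` assumes that every input dataset X^v (points × features,
feature spaces possibly disjoint) samples one latent manifold *M*
approximately uniformly. Nothing about the map from *M* into each
feature space is assumed linear; all geometry is estimated from
neighborhoods.

**Ambient spaces.** Distances are never measured in raw feature space.
Each dataset's own ambient space is its matrix reduced to
`min(50, rank)` component scores (PCA for continuous data; the
TF-IDF → truncated-SVD path, i.e. latent semantic indexing, is provided
for binarized accessibility matrices, with smoothed inverse document
frequency `idf(f) = log(1 + N/(1 + df_f))`). A shared feature space for
a dataset pair restricts both matrices to their feature-name
intersection (one canonical sorted order), stacks them, and reduces the
stack jointly — the concatenation is fit jointly rather than fitting one
dataset and projecting the other; with isotropic per-dataset noise the
two give nearly identical neighbor structure, and the joint fit is
symmetric in the inputs. No normalization is applied inside the shared
space construction (inputs are assumed normalized per modality
upstream); an optional `log1p` flag exists for count-like input.

**Manifold normalization (ρ, σ).** In every space, each point i's k
nearest-neighbor distances are normalized by
`m(i→j) = exp(−max(0, d_ij − ρ_i)/σ_i)` with ρ_i the distance to i's
nearest neighbor and σ_i solving `Σ_j m(i→j) = log2(k)` by bisection on
`(1e−8·mean_d, 1e3·mean_d]`, 64 iterations (≈2⁻⁶⁴ of the bracket, far
inside the 1e−5 tolerance asserted by the tests). Rows whose distances
are all zero get the fixed bandwidth floor σ = 1 (memberships are 1
regardless). This per-point calibration realizes a constant-radius ball
on *M*: membership mass per point is equal everywhere, so fuzzy sets
from spaces of different scale and dimensionality are commensurable.
Directed memberships are symmetrized with the probabilistic t-conorm
`a + b − ab`.

**Cross-dataset edges.** Inside a shared space, each point's k nearest
neighbors *from the other datasets* are calibrated exactly as above;
same-dataset pairs inside a shared space are discarded (own-space
geometry already covers them, on richer features). Per-point
calibration alone gives every point a membership-1 edge to its nearest
other-dataset point even when nothing over there matches, which falsely
anchors populations present in only one dataset. Cross memberships are
therefore gated at the shared space's own scale: per search direction,
the matched radius r0 is the 5th percentile of nearest cross-distances
(the best-matched points), a point is in-ball if its nearest
other-dataset point lies within 2·r0, the indicator is smoothed by
majority vote over the point's 15 nearest same-dataset neighbors in the
shared space (so whole regions are kept or cut coherently), and an edge
survives only if both endpoints are in-ball. Directions whose
nearest-distance distribution sits on a single scale — everything
matched, or one dataset uniformly noisy — are left untouched, which is
what makes the gate safe under strongly asymmetric noise.
A user-supplied cross-distance table (anchor points with known latent
positions) follows the plain per-point calibration with
`k = min(k, available)`; anchors are explicit statements that the pair
is comparable, so no gate applies.

**Assembly.** The MultiGraph's global index is the concatenation of the
datasets in input order. Duplicate edges arising from several spaces
merge by the same t-conorm, `μ = 1 − Π_s(1 − μ_s)`; each edge carries
the tag of the source with the largest contribution. Deleting every
shared space leaves all within-dataset edges bit-identical (tested).

**Layout.** The embedding minimizes
`Σ_e w_e [μ_e log(μ_e/ν_e) + (1−μ_e) log((1−μ_e)/(1−ν_e))]` with
`ν(r) = 1/(1 + a r^{2b})`, (a, b) least-squares fitted so ν matches 1
below `min_dist` and `exp(−(r−min_dist)/spread)` beyond. The per-edge
weight is ω_v for a within-dataset edge and the arithmetic mean
(ω_i + ω_j)/2 for a cross edge (symmetric, and it reduces to ω when the
two agree). Optimization is the standard edge-sampled stochastic
gradient scheme of this method family: each undirected edge is visited
from both heads with frequency ∝ μ, applies one attractive update and
`negative_sample_rate` repulsive updates against uniformly sampled
points, all scaled by w_e and a linearly decaying learning rate; edges
with `μ < μ_max/n_epochs` are never sampled. Negatives are drawn from
the union of the edge's endpoint datasets ("per-space repulsion"), not
from all points: the loss decomposes per ambient space, so overlaying
two datasets must be repulsion-neutral — with globally sampled
negatives, overlap doubles local density and costs more repulsion than
sparse cross edges can pay, and two datasets linked only by 1% anchors
settle side by side from any initialization instead of registering.
`repulsion_scope="global"` restores dataset-agnostic sampling for
comparison. A dataset with ω = 0 has its within-dataset edges removed
from both the layout edge list and the initialization graph before any
random draw, so its edge strengths cannot influence the result even
through the sampling stream.

**Initialization.** The d nontrivial eigenvectors of the symmetric
normalized Laplacian of the (weight-filtered) graph, computed per
connected component with shift-invert ARPACK around 0 and a fixed
starting vector (plain `which="SM"` Lanczos returns unconverged vectors
silently at loose tolerances); each component is rescaled to ±5 and
components are placed along the first axis with gaps of
`10 + (5 + 3√n)`-halfwidths, since the optimizer expands a component
roughly like √n and disconnected data should remain visually
disconnected. Eigensolver failure falls back to seeded uniform noise.

## Defaults that matter

| parameter | default | units / range | why |
|---|---|---|---|
| reduced dimension | 50 | components | field convention for both expression and accessibility |
| k (neighbors, own and shared spaces) | 15 | points | neighborhood-size convention of this method family |
| exact ↔ approximate kNN | 5000 | points per space | brute force below (deterministic), NN-descent above |
| min_dist / spread | 0.5 / 1.0 | embedding distance | looser packing than single-dataset practice; keeps mixed clusters legible |
| n_epochs | 500 (1 dataset) / 2000 (several), halved above 10⁴ points | epochs | cross-dataset registration propagates through sparse cross edges and converges several-fold more slowly than a single-space layout; 2000 sits on the observed plateau |
| negative_sample_rate | 5 | per attraction | standard repulsion budget |
| ω (weights) | 1.0 each; 0.8/0.2 with a designated reference | [0, 1] | reference convention: the higher-quality modality anchors the layout |
| ball gate | r0 = q0.05, slack 2, vote over 15 | shared-space distance | matched populations concentrate near the minimal cross scale; beyond twice it nothing matches |

All are exposed (`EmbeddingConfig`, function arguments, CLI flags).

## Synthetic scenarios — what they emulate, and what not

`make_swiss_roll_pair` — the canonical surface (t cos t, y, t sin t),
t ∈ [3π/2, 9π/2], y uniform on [0, 21], next to a 2-D rectangle whose
first axis is the normalized arc length s(t) ∈ [0, 1] (closed form
`(t√(1+t²) + asinh t)/2`) and whose second axis is y in the same units.
Anchor distances between 1% of each dataset's points are
|Δ position|. The roll genuinely folds: some pairs are closer in 3-D
than along the manifold (asserted by a test) — this is the nonlinearity
the method must undo. Only the lengthwise coordinate is anchored, so
transverse registration emerges solely from the layout; alignment of
the joint embedding plateaus around 0.3, well below the 0.5 of a
perfect overlay.

`make_split_image_pair` — left/right 28×15 halves of 28×28 class
images (420 features each) overlapping in a 28×2, 56-feature sliver
identified by shared feature names; Gaussian noise with sd equal to the
image dynamic-range maximum is added to the first half only. Class
prototypes are **synthetic**: smooth random fields thresholded to
~30%-coverage binary strokes (emulating the near-binary pixel
statistics of handwritten digits), chosen as a max-min-distance subset
of 3× candidates (digit classes are mutually distinct), with half the
sliver pixels replaced by one common stroke pattern in every class (the
sliver is ambiguous between classes). Per-pixel within-class jitter
(sd 25 of 255) stands in for handwriting variability. Not emulated:
stroke topology, correlated deformations, and the ~70k-sample scale of
real digit collections — at n = 2000 the noisy-sliver registration is
noticeably harder than it would be at full scale, and transfer accuracy
fluctuates by a few points across generator seeds.

`make_cluster_overlap_pair` — Gaussian clusters around latent
centroids (max-min-separated, sd 3 vs cluster sd 1, latent dim 10),
observed through dataset-specific random linear maps into 60 features
of which 20 come from one map shared by both datasets; dataset B keeps
m of A's clusters and replaces the rest with fresh ones. Probes
exactly the false-alignment behavior the ball gate exists for. Not
emulated: count noise, library-size effects, nonlinear feature maps.

Passing tests on these generators demonstrates the geometry of the
method — nonlinear unrolling, use of unshared features, robustness to
unmatched populations — not performance on real sequencing noise.

## Numerical choices and degenerate inputs

- PCA uses a deterministic sign convention (largest-|loading| entry of
  each component positive); the full SVD solver below 1500 effective
  dimensions, randomized (seeded) above.
- All-zero TF-IDF rows and empty feature intersections are errors that
  name the offender; an intersection smaller than the target dimension
  lowers it with a logged warning; `k ≥ n` is clipped with a warning.
- The layout kernel is single-threaded numba with an xorshift64 RNG
  advanced sequentially; runs are bitwise reproducible for a fixed
  seed, and the kernel is resumable so loss snapshots do not perturb
  the random stream.
- ν is clamped to [1e−12, 1 − 1e−12] in loss evaluation; gradient
  components are clipped to ±4 per dimension.
- Harmonic label transfer solves the grounded-Laplacian system with
  conjugate gradients to 1e−8 (SPD whenever every component containing
  unlabeled points has a label; components without labels are flagged
  unassignable), with sparse LU as fallback; labeled rows are clamped
  exactly and solved rows renormalized to sum to 1.
- The structure metric subsamples above 10⁶ point pairs with a seeded
  generator.

## Open choices made here

- Cross-edge weight = mean of the two datasets' ω (attractive and
  repulsive terms both scaled; a flag restricts scaling to attraction).
- Shared-space PCA fit on the concatenation, not fit-on-one/project.
- The ball gate is this package's realization of the per-space metric;
  `calibration="point"` disables it.
- Per-space negative sampling is the default; see above for why.
- An edgeless graph performs no updates at all (negative sampling is
  edge-driven), and returns the initialization with a warning.

## Limitations

- The uniform-sampling assumption is shared with the wider method
  family; strongly density-biased datasets will distort neighborhoods.
- Alignment between datasets linked only by sparse anchors registers
  the anchored coordinate(s) only; unanchored directions overlay
  loosely.
- The ball gate's matched-scale estimate assumes at least ~5% of the
  querying dataset has true counterparts; below that the gate degrades
  gracefully to per-point behavior but false anchoring can return.
- 2-D embeddings of many clusters crowd; graph-based label transfer is
  the more reliable consumer when clusters are numerous.
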