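# comanifold

Integration and joint dimensionality reduction of multimodal datasets
that live in **different feature spaces** — e.g. scRNA-seq gene
expression next to scATAC-seq peak accessibility, spatial panels, or DNA
methylation — for computational biologists who need one embedding and one
neighborhood graph spanning all of their datasets without discarding the
features unique to each.

## The method

Datasets X¹, X², … (cells × features, with possibly no features in
common) are assumed to sample one latent manifold *M*. The pipeline:

1. **Ambient spaces.** Each dataset's own space is its PCA/SVD reduction
   (50 components by convention; TF-IDF weighting + SVD for binary
   accessibility). For every pair of datasets with overlapping feature
   names, a *shared feature space* is built by restricting both to the
   intersection and jointly reducing the stack. Explicit cross-dataset
   distances for a subset of point pairs (anchors) may be supplied
   instead of, or in addition to, shared spaces.
2. **Manifold normalization.** Within every space, distances from point
   *i* are normalized by a local connectivity radius ρᵢ (distance to its
   nearest neighbor) and a bandwidth σᵢ calibrated so that
   Σⱼ exp(−max(0, dᵢⱼ − ρᵢ)/σᵢ) = log₂ k over its k nearest neighbors —
   realizing a constant-radius ball on *M* and making memberships
   comparable across spaces of different scale and dimensionality.
   Directed memberships are symmetrized with the probabilistic t-conorm
   a + b − ab.
3. **MultiGraph.** The per-space fuzzy sets are merged into one
   symmetric graph over all N = Σ nᵥ points: within-dataset edges from
   each dataset's own space, cross-dataset edges from shared spaces
   (gated at the shared space's matched scale, so populations present in
   only one dataset are not falsely anchored to the other) and/or the
   anchor table, duplicates merged by the same t-conorm.
4. **Embedding.** Coordinates minimize the weighted fuzzy cross entropy
   Σₑ wₑ [μₑ log(μₑ/νₑ) + (1−μₑ) log((1−μₑ)/(1−νₑ))] between graph
   memberships μ and embedding memberships ν(r) = 1/(1 + a r²ᵇ), by
   stochastic gradient descent over edges with negative sampling from a
   spectral initialization. Per-dataset weights ω ∈ [0, 1] modulate each
   dataset's influence (convention: 0.8 for a designated reference
   modality, 0.2 otherwise).

Downstream, the package provides 5-NN and harmonic-function label
transfer and four benchmark metrics: transfer balanced accuracy,
mean silhouette, alignment (dataset mixing among nearest neighbors), and
structure (Pearson correlation of high- vs low-dimensional distances).
The graph exports to Matrix Market for external clustering or
pseudotime tools.

## Worked example

A 3-D Swiss roll and a 2-D rectangle sample the same rectangular
manifold; the latent position of 1% of the points provides anchor
distances:

```python
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from comanifold import (EmbeddingConfig, alignment_score, integrate,
                        make_swiss_roll_pair)

scenario = make_swiss_roll_pair(n=1000, anchored_fraction=0.01, seed=0)
config = EmbeddingConfig(seed=0)
graph, embedding = integrate(
    scenario.blocks, cross=scenario.cross, config=config, n_dims=3
)
print(f"graph: {graph.n_points} points, {graph.matrix.nnz} directed edges")
for ds in ("roll", "rect"):
    pc1 = PCA(n_components=1).fit_transform(embedding.for_dataset(ds)).ravel()
    r = spearmanr(scenario.positions[ds], pc1).statistic
    print(f"{ds}: |spearman(position, PC1)| = {abs(r):.3f}")
print(f"alignment = {alignment_score(embedding):.3f}")
```

Output:

```
graph: 2000 points, 34162 directed edges
roll: |spearman(position, PC1)| = 0.994
rect: |spearman(position, PC1)| = 0.966
alignment = 0.236
```

The first principal coordinate of each dataset's embedded points tracks
the true manifold position almost monotonically — the roll has been
unrolled nonlinearly — and roughly a quarter of every point's five
nearest embedded neighbors come from the other dataset, so the two
datasets are genuinely interleaved rather than placed side by side
(without the anchors the same pipeline leaves them fully separate,
alignment ≈ 0).

The same pipeline is available from the shell:

```bash
comanifold simulate swissroll --n 1000 --seed 0 --out sim/
comanifold integrate --data sim/roll.tsv --data sim/rect.tsv \
    --cross-distances sim/cross_distances.tsv --seed 0 --out run/

# a labeled scenario, with the benchmark metrics afterwards
comanifold simulate overlap --m 5 --seed 0 --out sim2/
comanifold integrate --data sim2/A.tsv --data sim2/B.tsv --seed 0 --out run2/
cat sim2/A.labels.tsv sim2/B.labels.tsv > sim2/labels.tsv
comanifold metrics --embedding run2/embedding.tsv \
    --labels sim2/labels.tsv --query-dataset B --out metrics/
```

`integrate` writes `embedding.tsv`, the graph as
`multigraph.mtx` (+ index and edge-provenance TSVs), and a `config.json`
sidecar that reproduces the run exactly.

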