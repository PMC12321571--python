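# arcquant

Quantitative image-analysis pipeline for the **Arc**, the expanded
subventricular zone (SVZ) of neonatal gyrencephalic brains, which feeds
postnatal migratory streams of GABAergic interneurons into the cortex.
The package reimplements, as a tested and reusable library, the
image-derived computations of a comparative neurodevelopment study of this
structure:

- **Multiplexed smFISH quantification** (`arcquant.fishquant`) — each probe
  channel is binarised with a Rényi-entropy automatic threshold; a cell's
  expression of gene *g* is the *pixel-percentage* value
  `100 · |probe ∧ ROI| / |ROI| ∈ [0, 100]`. Per gene, values at or below the
  across-cell median are zeroed as background; the matrix is
  log-transformed, scaled, reduced by PCA (all components kept), clustered
  with Leiden, embedded with UMAP, and clusters are assigned to interneuron
  subtypes (NKX2.1⁺MAF1⁺, SST⁺LHX6⁺, COUP-TFII⁺SP8⁺, COUP-TFII⁺TBR1⁺,
  COUP-TFII⁺CALB2⁺, VIP⁺GAD1⁺, SATB2⁺ EN) by marker-gene rules.
- **Neighborhood interaction analysis** (`arcquant.neighborhood`) — a
  histoCAT-style permutation test. Cells closer than 4 px are neighbors;
  for an ordered type pair (A, B) the interaction score is the mean number
  of B-neighbors per A-cell, tested one-tailed against labels permuted
  within the image: `p = (1 + #{null ≥ obs}) / (1 + n_perm)`. Across
  images a pair is kept if significant (P < 0.05) in ≥ 30% of images and
  present in ≥ 90%. Includes topographic mapping of cells along a
  migratory-stream polyline.
- **Section morphometrics** (`arcquant.morphometry`) — Arc area ratio and
  tier decomposition, gyrification index `GI = L_full / L_outer`,
  thresholded positive-area fractions, DCX tier intensity profiles,
  Pearson correlation (e.g. GI vs Arc area ratio), and the serial-section
  volume estimator

  `V = Σₖ (A_{k−1} + A_k + √(A_{k−1}·A_k)) · h / 3`,

  the conical-frustum (Cavalieri-type) sum over consecutive section areas,
  exact for stacks of frusta.
- **Synthetic ground truth** (`arcquant.synthetic`) — generators for every
  input: probe stacks with per-(type, gene) probe-pixel probabilities and
  background speckle, CSR / Neyman–Scott clustered cell maps, analytically
  sectioned solids, folded cortical contours and exact region masks, so
  every stage is testable with planted truth and no data download.

## Worked example

```python
import numpy as np, pandas as pd
import arcquant as aq

# serial-section volume of a cone sliced apex-to-base
series = aq.generate_section_profile(
    aq.SolidSpec("cone", n_sections=9, spacing=0.4, radius=1.5, height=3.2))
aq.estimate_volume(series)            # 7.539822  (= pi r^2 H / 3 exactly)

# gyrification index of a folded cortical outline
contour = aq.generate_contour(10.0, 2.0, 8, n_points=2048)
aq.gyrification_index(contour)        # 1.2332  (quadrature truth 1.2332)

# planted homotypic attraction detected by the permutation test
spec = aq.InteractionSpec(modes={("A", "A"): "attract"},
                          cluster_sd=2.0, mean_offspring=10.0)
results = []
for i in range(20):
    cells = aq.generate_cell_map(100, {"A": 0.5, "B": 0.5}, interaction=spec,
                                 image_size=(40, 40), seed=i)
    graph = aq.build_neighbor_graph(cells, distance_threshold=4.0)
    labels = pd.Series(cells["type"].to_numpy(),
                       index=cells["cell_id"].to_numpy())
    results.append(aq.permutation_test(graph, labels, ("A", "A"),
                                       n_permutations=1000, seed=100 + i))
decision = aq.aggregate_images(results)[0]
```

This prints, for the first image, an observed A→A score of 7.84 against a
permutation-null mean of 2.97 (p = 0.0010): clustered A-cells touch far
more same-type neighbors than label shuffling predicts. The aggregation
rule reports the pair significant in 100% of the 20 images and present in
100%, hence `keep=True` — the planted attraction survives the 30% / 90%
filter that decides which edges appear in the cross-image interaction
graph.

A `arcquant` command-line entry point wraps the same functions
(`arcquant simulate …`, `arcquant quantify`, `arcquant cluster`,
`arcquant assign`, `arcquant neighborhood run`, `arcquant morpho …`); every
subcommand takes explicit seeds and writes CSV/TIFF.

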