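# smvk — spatial multi-omics analysis of microvascular invasion in HCC

Microvascular invasion (MVI) — tumor cells inside peritumoral
microvessels — marks aggressive hepatocellular carcinoma (HCC). Spatial
transcriptomics (ST), spatial metabolomics (SM) and multiplex
immunofluorescence (MIF) together let one ask *where* the biology of
MVI lives: which malignant subpopulation occupies the tumor lesion,
how the capsule's fibroblasts are arranged relative to the tumor
boundary, and which metabolites track them. `smvk` implements that
analysis as a reusable, tested pipeline for researchers working with
Visium-style spot lattices, MSI rasters and multi-channel IF images:

- **Boundary geometry** — on the hex lattice every spot has six
  neighbors `(r, c±2), (r±1, c±1)`; a region spot is a *boundary* spot
  iff any of the six is missing or belongs to another region, and each
  outside spot gets its shortest Euclidean distance
  `d(s) = min_b ‖x_s − x_b‖` to the boundary set.
- **Triple-positive marker panel** — per-cluster marker statistics
  (log2FC, pct.1, pct.2, Wilcoxon p, BH q), then the four-step
  selection: top-30 by log2FC → pct.1 > 0.8 → seed = argmax(pct.1 −
  pct.2) → companion by Pearson correlation in a bulk reference →
  a-priori marker (GPC3), with a full audit trail.
- **Signature scoring** — module scores: mean normalized expression of
  a gene set minus expression-matched bin controls, and score-vs-
  boundary-distance gradients (Spearman/Pearson).
- **SSC metabolite segmentation** — spatially-aware shrunken centroids
  (Gaussian neighborhood smoothing, soft-thresholded per-ion
  statistics, r=1, k=15, s=3), top-10 marker ions per segment, and
  metabolite-class enrichment via Fisher's exact odds ratios.
- **Cross-modal integration** — least-squares similarity registration
  from landmarks, pixel→spot aggregation, and per-sample/pooled
  correlation of ion intensities with cell-type proportions, signature
  scores and boundary distances.
- **MIF quantification** — rolling-ball background subtraction (15 px),
  mean+3SD channel thresholds, DAPI nuclear segmentation with 3 µm
  cytoplasmic expansion and a 25–200 µm² object filter, and
  co-localization ratios `100·|STMN1+HMGN2+GPC3+|/|GPC3+|` compared
  between groups with a t test.

Because the original patient cohorts are not redistributable, the
package ships a first-class synthetic-cohort generator
(`smvk.synthetic`) that plants every effect the pipeline is meant to
detect — a triple-positive subpopulation enriched in MVI+, a distal
iCAF gradient in the capsule, a taurine field coupled to iCAF at
ρ = 0.6, suppressed glycerolipids in MVI+ tumor pixels, and known
per-cell MIF positivity — with the ground truth exported to
`truth.json`. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

```python
import numpy as np
from smvk.synthetic import generate_cohort
from smvk.pipeline import boundary_field, panel_from_sample, taurine_icaf_correlations

cohort = generate_cohort(seed=1, groups=("MVI_POS", "MVI_POS", "MVI_NEG", "MVI_NEG"))
sample, raster, truth = cohort.samples[0]

boundary, dist = boundary_field(sample, "T")
print(len(boundary.boundary_spots), len(boundary.core_spots))
# 74 368            -> 74 of the 442 tumor spots touch the lesion rim

panel, stats = panel_from_sample(sample, cohort.reference_bulk)
print(panel.genes)
# ('STMN1', 'HMGN2', 'GPC3')   -> the planted triple, recovered from counts

per_sample, pooled = taurine_icaf_correlations(cohort)
print(round(float(pooled["mean_rho"].iloc[0]), 4))
# 0.5958            -> pooled taurine-iCAF Pearson r across the four
#                      tumor sections, against a planted rho of 0.6
```

The numbered drivers under `analysis/` run the same stages as a
narrative, writing tables to `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_boundary_geometry.py --seed 1
...
python analysis/06_mif_quant.py --seed 1
# Mean triple-positive ratio: MVI+ 28.7% vs MVI- 4.6% (planted 30% vs 5%);
# Student t = 24.41, p = 1.67e-05
```

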