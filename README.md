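# mexquant

Quantitative single-cell metallomics for laser-ablation ICP-TOFMS imaging:
from multichannel elemental count images and gelatin-microdroplet calibration
standards to **absolute per-cell metal amounts (fg)**, phenotype clusters,
and pixel-level quantitative maps.

It is written for analysts working with multiplexed elemental tissue images
(imaging mass cytometry / LA-ICP-TOFMS at ~1 µm pixel size) who want a
scriptable, reproducible pipeline: every stage is an importable function, a
thin `mexquant` CLI chains them for batch work, and a synthetic-tissue
generator with known ground truth makes the whole chain verifiable offline.

## The model

A pixel of an elemental image holds detector counts `I(x, y)` for one
isotope. Microdroplet standards of known volume `V ≈ 400 pL` and
concentration `c` (µg/L) carry a known absolute amount

```
m [fg] = c [µg/L] · V [pL] · 10⁻³            (aqueous density 1 g/mL)
```

Fully ablating each droplet and integrating its counts gives points
`(m, counts)`; ordinary least squares over a blank + 5 standards yields the
external calibration

```
counts = S·m + b ,     S = calibration factor [counts/fg]
```

Per-cell amounts follow by inverting this affine map on each cell's
integrated counts (cells from a watershed segmenter or any imported mask);
per-cell detection limits come from Currie's treatment of Poisson blank
counts `B` measured on unexposed control tissue:

```
L_C = 1.645·√(2B)   (decision threshold, counts)
L_D = 2.71 + 4.65·√B   (detection limit, counts)   →   LOD = L_D / S  [fg]
```

Phenotyping follows the Phenograph construction — a Jaccard-weighted
k-nearest-neighbor graph on size-normalized, scaled single-cell features,
partitioned by Leiden — with UMAP embeddings, per-cluster expression
heatmaps and pairwise Mann–Whitney U tests (exact for small samples) on
quantified amounts. Pixel-level analysis mirrors the same quantification on
k-means-classified elemental maps with Spearman correlation summaries.

## Worked example

```bash
python examples/end_to_end_quantification.py
```

prints (machine-exact values vary only with the seed):

```
simulated 200 cells, true mean 2.08 fg 59Co/cell
segmented 199 objects
recovered mean 2.11 ± 1.69 fg/cell over 199 cells
median per-cell relative error 2.4% (population mean error 1.16%)
procedural LOD: 0.041 fg/cell (blank mean 15.0 counts, n=200 blank cells)
```

Reading: 200 disk cells with lognormally distributed cobalt amounts were
rendered with Poisson counting noise and 1% hot pixels; after hot-pixel
removal, watershed segmentation and calibration with the true factor
(500 counts/fg), the population mean comes back within ~1% and a typical
cell within ~2.5% — the residual is counting statistics plus segmentation
boundary error. The LOD line converts blank-tissue counts into the smallest
amount distinguishable from the staining background.

Other narrative examples: `examples/droplet_calibration.py` (calibration
factor from a standard array), `examples/phenotype_clusters.py` (clustering,
heatmap, rank tests), `examples/pixel_maps.py` (pixel k-means and Spearman
maps). The same stages run from the shell:

```bash
mexquant simulate tissue --out demo --seed 0
mexquant segment --images demo --membrane 161Dy --out demo/mask.png
mexquant run pipeline.toml        # full chain from one validated TOML config
```

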