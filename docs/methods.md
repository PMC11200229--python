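# Methods

## Scope and conventions

`mexquant` converts multichannel elemental count images (LA-ICP-TOFMS /
imaging mass cytometry, 1 µm/pixel convention) into absolute per-cell and
per-pixel metal amounts, phenotype clusters, and summary statistics. All
rasters are 0-based, row-major, origin top-left; geometry is kept in pixels
and converted to µm only through `pixel_size_um`. Channel identity is the
isotope string; marker names live in the panel config only. Imported masks
are relabeled to consecutive `1..N` so joins between mask, cell table and
cluster labels are stable. Raw-spectrum processing (mass calibration, peak
fitting, baseline subtraction) is upstream instrument-software territory and
out of scope; the pipeline starts from per-isotope count images or per-pixel
CSV tables.

## Preprocessing

**Hot pixels.** A pixel is replaced by the median of its
`neighborhood_size² − 1` neighbors (center excluded) when it exceeds that
median by more than `threshold` counts. Defaults: 3-pixel window,
threshold 50 counts — the workflow's standard settings for 1 µm maps. The
threshold is read as an *absolute excess over the neighbor median*; the
median reference (rather than the mean) keeps a spiked neighbor from
masking a second spike. All window operators use reflect padding so border
pixels are not darkened. The filter is applied to channels that feed
quantification; segmentation channels instead get a median filter (radius
1–2), which suppresses spikes anyway and does not erode small bright nuclei
the way an absolute-excess rule can at sharp staining edges.

**Smoothing, stacking, tiling.** Gaussian smoothing (normalized kernel,
mass-conserving) and median filtering are optional speckle controls.
Percentile contrast rescaling exists for segmentation stacks only —
quantification always sees raw counts. Stacks can be split into ~300-pixel
tiles with offsets for exact reassembly.

## Segmentation

The native segmenter is a seeded watershed on the 2-channel
(membrane, nucleus) stack: foreground by triangle thresholding of the
*unsmoothed* membrane+nucleus sum (triangle suits rasters that are mostly
background — Otsu lands mid-plateau and halves the masks; thresholding the
unsmoothed sum avoids a smoothing halo that would otherwise make measured
cell areas, and hence per-area densities, cell-size dependent); seeds from
distance-transform peaks of the triangle-thresholded, Gaussian-smoothed
nucleus channel with minimum separation of half the expected diameter;
region growth by watershed on the inverted smoothed membrane channel,
constrained to the foreground. It exists so the pipeline runs end to end
without external deep-learning tools; masks from any external segmenter
(PNG/TIFF) are imported instead when supplied and take precedence.

Object QC mirrors standard single-cell practice: objects touching the
raster border are removed (truncated cells), and objects outside
[10, 10 000] px at 1 µm/px are dropped — bounds bracketing plausible cells
around the ~10 µm average diameter; both configurable. Features per cell:
centroid, area, area-equivalent diameter (µm), eccentricity, and per-isotope
integrated (exact pixel sums) and mean counts. Intensity is conserved
exactly: cell sums plus background equal the image total.

## Calibration and quantification

Droplet amounts use `m[fg] = c[µg/L] · V[pL] · 10⁻³`, assuming density
1 g/mL for aqueous gelatin. The calibration is an ordinary least-squares
line of integrated counts on amount over a blank + 5 standards; slope
(counts/fg), intercept, R² and the spanned linear range are reported.

The slope's uncertainty is a *counting-statistics* standard error: each
standard's count variance is estimated by the count itself (Poisson), giving
`SE² = Σ (xᵢ−x̄)²·countᵢ / Sxx²`. With only ~6 points this is far more
stable than residual-based OLS errors, whose 4-degree-of-freedom variance
estimate badly under-covers for heteroscedastic counts.

Quantification inverts the affine map, `amount = (counts − b)/S`, floored at
zero (floored cells are logged). Intercept subtraction is on by default and
switchable: when the intercept comes from droplet integration windows
(~200 µm) its background contribution has no counterpart in an ~80 px cell,
and subtracting it biases cellular amounts low — in that situation the
slope-only conversion is correct, or standards should be blank-corrected
before fitting.

Droplet integration supports two routes. *Known positions* (spotted arrays
have known geometry): fixed disk windows at the given centers, which also
measures blanks and faint standards. *Detection*: hierarchical
triangle-thresholding of the smoothed image (detect, mask, re-threshold the
residual) because standards span ~2 orders of magnitude and a single global
threshold misses the faint levels; footprints are refined at 30% of each
local peak, dilated 2 px to capture ablation spread, and flagged when the
equivalent diameter deviates >50% from the expected ~200 µm or the footprint
is elongated (eccentricity > 0.7, the signature of merged droplets — two
fused equal droplets change the equivalent diameter by only √2 ≈ 41%, below
the size rule alone).

**Detection limits.** With B the mean blank integrated counts per cell from
unexposed, stained control tissue, the Currie formulation gives the decision
threshold `L_C = k_C·√(2B)` (paired blank subtraction; `k_C = 1.645` for a
5% false-positive rate) and detection limit `L_D = 2.71 + 4.65·√B`, both in
counts and divided by the slope for fg. The constants are configurable; a
Monte-Carlo helper (`currie_false_positive_rate`) verifies the advertised
false-positive rate by simulating paired Poisson blanks.

## Phenotyping

The preparation order is fixed and recorded on the feature matrix:
size-normalization (integrated counts ÷ cell area in µm², removing cell-size
effects) → per-channel upper-percentile outlier *removal* (default 99.5%;
removal, not winsorization, keeps the matrix consistent with the cell
table) → per-channel min–max scaling to [0, 1] (z-score optional; constant
channels map to 0 with a warning). Clustering is the Phenograph
construction: Euclidean kNN graph (k = 30), edges reweighted by the Jaccard
overlap of closed neighbor sets, Leiden community detection
(RB-configuration, resolution 1.0, fixed seed); defaults are Phenograph's
published ones. Labels are re-indexed by descending cluster size so runs are
comparable. UMAP (fixed seed) is visualization-only. Pairwise cluster
comparisons use the two-sided Mann–Whitney U — exact when
min(n₁, n₂) ≤ 8 and tie-free (the exact null does not handle ties),
tie-corrected normal approximation otherwise — with Bonferroni adjustment
over the K(K−1)/2 pairs. Endogenous elements (e.g. Fe) may serve as
phenotyping features but are excluded from quantification outputs by
default, since intrinsic elements lack a valid external calibration in
stained tissue.

## Pixel analysis

k-means (k-means++ init, best of 10 starts, fixed seed) on per-pixel count
vectors, z-standardized per channel by default so high-count channels do not
dominate; reported cluster means are always raw counts, and cluster ids are
ordered by ascending mean of the quantified channel so replicate runs align.
Replicate images aggregate per-cluster quantified means as mean ± sd.
Spearman rank-correlation matrices are symmetric, unit-diagonal and exactly
invariant under strictly monotone per-channel transforms. No spatial
regularization is applied.

## Synthetic data: what it emulates and what it does not

The generator renders non-overlapping disk cells (radius ~N(5, 1) µm clipped
to [3, 8]) with nuclear cores, a membrane/cytoplasm channel, three phenotype
marker channels and a metal channel on a 500×500 px raster. The measurement
model is: expected integrated counts of an object = calibration slope ×
true amount; the expectation is spread over the footprint with a
plateau-plus-3-px-edge-ramp thickness profile (support strictly inside the
object, so noiseless totals are exact); pixel counts are Poisson; hot pixels
of +500 counts are injected at 1% density on the metal channel at recorded
positions.

Default conditions: 200 cells; per-phenotype lognormal amounts with mean
2.4 fg and sd 1.8 fg (the headline single-cell scale), truncated at 10 fg to
match the plausible observed per-cell range; amounts scale with relative
cell area (volume-like accumulation; the area factor averages to 1 so the
population mean is preserved); slope 500 counts/fg; marker profiles
25 counts/px on-target vs 8 counts/px off-target — nonzero off-target
staining is what real multiplexed antibody panels show, and it also keeps
per-channel counting noise comparable, since strongly anisotropic
within-phenotype noise fragments kNN-graph communities for any
Phenograph-style clustering.

Not modeled: aerosol dispersion blur (available separately via the Gaussian
filter), detector dead time, non-disk cell shapes, within-phenotype staining
heterogeneity, spatial tissue architecture. Passing the synthetic recovery
suite therefore demonstrates correctness of the *computational chain* under
Poisson counting statistics — not robustness to every artifact of real
tissue data, where segmentation quality is the dominant error source.

## Validation suite and problem sizes

`mexquant.validation` (driven by `scripts/acceptance.py` and the test suite)
recomputes: end-to-end recovery on 200 cells (population-mean error,
median per-cell error, recall, clustering ARI); hot-pixel selectivity on
2 500 injected spikes; calibration exactness (noiseless) and 3-SE slope
coverage over 100 Poisson refits plus a full simulated-array recovery at
50 counts/fg; the Currie false-positive rate on 10⁵ paired Poisson blanks at
B = 100; two-region k-means recovery and Spearman monotone invariance.
These sizes keep the whole suite under a minute on one CPU while leaving
every stochastic check with comfortable statistical resolution.

## Known limitations

- The watershed segmenter is a capable stand-in, not a replacement for
  trained neural segmentation on real tissue morphology; import external
  masks for production analyses.
- Day-to-day drift is handled by day-specific calibration curves only; no
  cross-day drift model. No isotope-interference correction (upstream TOF
  processing territory).
- Threshold-based droplet detection cannot find blank droplets (they carry
  no signal); use known-position integration for full series.
- Leiden at resolution 1.0 can split elongated feature-space clusters;
  resolution is exposed, and the cluster heatmap is the intended tool for
  judging whether neighboring clusters are one phenotype.
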