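# Methods

This note documents the models, numerical choices and limitations behind
`msipipe`. It is the place to look when a default needs justifying or a
behavior at a degenerate input needs explaining.

## Data model

A MALDI-TOF imaging dataset is held as a `Datacube`: an
`n_pixels x n_channels` non-negative intensity matrix, a strictly
increasing shared m/z axis (Daltons), and integer pixel coordinates
(x, y), 1-based as stored in imzML. The grid may have holes; unmeasured
pixels are represented as NaN + mask in every spatial view (`MzImage`),
never as silent zeros, because zero-filling biases both contrast scaling
and mask correlations. Rendering places y increasing downward, matching
the common MSI viewer convention.

imzML is read and written through pyimzml. Continuous-dialect files map
directly onto the cube. Processed-dialect files (per-spectrum axes) are
resampled onto a common axis: the union of all spectrum axes binned at
the median channel spacing, linear interpolation of each spectrum, then a
per-spectrum rescale so each spectrum's trapezoid integral over m/z is
conserved exactly. The rescale makes the resampling conservative by
construction instead of relying on the axes being fine enough. Whether a
file was profile or centroided is recorded in `meta` and not otherwise
acted on. The `.ibd` SHA-1 recorded in the imzML header is verified on
read; a missing `.ibd`, a duplicated pixel coordinate and a checksum
mismatch each raise their own exception type.

## Pre-processing

* **Normalization.** TIC normalization divides each spectrum by the sum
  of its intensities; median normalization by the median of its positive
  intensities. Both are per-spectrum scalings and agree up to a constant
  factor per spectrum. The normalized cube is rescaled by the dataset
  median divisor by default so intensities stay on an interpretable
  scale; `target_scale=1.0` gives unit-TIC spectra. In unit-scale mode
  normalization is exactly equivariant under a global intensity rescale;
  in median-target mode the global factor survives by design (the target
  itself scales). Spectra with a zero divisor (off-tissue pixels) are
  left unchanged and flagged rather than erroring, and re-normalizing an
  already-normalized cube warns and no-ops. The choice between TIC and
  median is left to the user; the preprocess stage renders one exemplary
  m/z-image under each so the choice can be made visually.
* **Baseline.** Morphological opening (rolling minimum then rolling
  maximum) over an odd window, lightly smoothed, clipped from below by
  the spectrum, subtracted. Parameter-light and standard for MALDI
  spectra; window default 101 channels, which must exceed the widest peak
  to be preserved. The operation is idempotent to well under 1% of TIC.
* **Smoothing.** Moving average with reflective edges; odd window,
  default 5; window 1 is the identity; TIC conserved to <0.1%.
* **Order.** The default stage order is baseline → smoothing →
  normalization, configurable; there is no canonical order for these
  steps and each is individually switchable.

Spectra recalibration is out of scope.

## Peak picking

Picking on the dataset mean spectrum alone is fast but insensitive: a
peak confined to a fraction *f* of the pixels is diluted by 1/*f* in the
mean (the 100×100-grid, 10×10-block worked example gives exactly 100×).
The dataset peak list is therefore built by consensus:

1. **Spectrum-wise picking** — local maxima whose prominence exceeds
   `snr` × a robust noise scale (1.4826 × MAD of the detail residual
   after a 5-channel moving average). Prominence is a shape-aware
   criterion; the cost is O(n log n) per spectrum. For noiseless input
   the threshold degenerates to a tiny floor so every genuine apex is
   returned. This picker stands in for sparse-approximation methods whose
   formulation is outside this package's scope.
2. **Alignment to the mean spectrum** — each picked m/z snaps to the
   nearest local maximum of the dataset mean spectrum within `tol`
   (default 0.5 Da, appropriate for protein-range TOF; settable).
   Unmatched peaks are kept unmoved and flagged.
3. **Consensus filter** — aligned peaks are grouped along m/z (a gap
   larger than `tol` starts a new group; the reported m/z is the
   intensity-weighted group mean) and a group is kept iff present in at
   least `min_fraction` of the spectra, default 1%. Presence is counted
   *after* alignment. The filter is monotone in `min_fraction`.

For modeling, 50–200 dataset peaks is the practical target; when the
consensus list overshoots, the spectrum-wise SNR threshold is raised
(factor 1.5 per iteration) until it fits — presence-qualified peaks are
never dropped by any other mechanism.

**Uphill masses alignment** shortens hit lists after analysis: each m/z
moves stepwise to the strictly-higher neighboring channel of the mean
spectrum until none exists; values on a flat plateau drift to the
plateau's lowest-m/z channel (the deterministic tie-break). Flank
variants of one peak thereby merge into its apex; the operation is
idempotent and every output is a (non-strict) local maximum.

## Segmentation

Features for clustering are the consensus-peak window sums per pixel
(`peak_features`), deliberately not all channels: segmentation rarely
needs more than the peak set, and fewer features mean less noise and
faster distance computations. Four variants:

* **Plain k-means** — k-means++ init, 10 restarts, seeded.
* **Hierarchical** — PCA-reduce to the smallest component count reaching
  `pca_variance` (default 0.70) explained variance, then agglomerative
  clustering (Euclidean/Ward default). Agglomeration materializes an
  n×n distance matrix, so cubes beyond a configurable pixel guard
  (default 20,000) are refused with an explicit error instead of
  exhausting memory.
* **Denoise-then-cluster** — every peak image is bilateral-filtered
  (edge-preserving), then k-means on the denoised features.
* **Spatially-aware k-means** — each pixel's feature vector is
  concatenated with a Gaussian-weighted average of its neighbors within
  `radius` (σ = radius/2). In adaptive mode each neighbor is additionally
  down-weighted by exp(−d²_spectral/h²), h² being the median squared
  spectral distance between adjacent pixels, so the average does not leak
  across tissue edges. Neighborhood sums are computed by shifted-grid
  accumulation: O(n·radius²) time, O(n) memory, no pairwise pixel matrix.
  `radius = 0` dispatches to plain k-means exactly. The exact
  neighborhood constructions published for the denoising and
  spatially-aware methods are not reproduced here; these are documented
  surrogates with the same intent.

PCA loadings use a deterministic sign convention (largest-magnitude entry
of each loading positive). Querying "highest-loading m/z per component"
emits a warning: high loading does not guarantee the m/z-image
co-localizes with the score image, a known failure mode of loading-based
interpretation.

Cluster count k is user-specified; no model selection is attempted.
Labels are 1..k with a fixed categorical palette; an empty cluster
triggers an explicit warning.

## Interpretation

For a chosen cluster, a binary spatial mask is correlated against *every*
channel image (all m/z values, not just picked peaks — weak ions that
never survive picking can still colocalize cleanly). Pearson r is
computed vectorized over measured pixels; the two-sided p-value comes
from the t transform with n−2 degrees of freedom. Selection defaults to
the raw-p rule (p < 0.05 and r > 0); because tens of thousands of
channels are tested, a Benjamini–Hochberg q is always reported alongside
and `use_q=True` switches selection to it. Anti-correlated channels are
reported (sorted to the bottom) but never "selected": colocalization
means positive association here. Channels constant over measured pixels
have no defined correlation, and channels that are numerically silent
(maximum below 1e-12 × the cube maximum) carry no evidence worth
ranking; both are flagged `degenerate` with r = 0, p = 1 — NaN never
propagates. Records with near-tied r (within 1e-6, e.g. the flank
channels of one peak, which share their apex's spatial pattern) are
ordered secondarily by q90 intensity so apexes precede tails in
reports. Nominal Pearson p-values ignore spatial
autocorrelation and are therefore anti-conservative; no spatial
correction is attempted beyond the optional BH adjustment, and the values
should be read as ranking scores more than calibrated error rates.

Related-ion annotation flags m/z pairs separated by 1 Da (isotope),
16 Da (oxidation), 17 Da (ammonia loss) or 18 Da (water loss) within a
0.2 Da tolerance; such internally consistent patterns raise confidence
that a hit list reflects real chemistry.

The report stage writes one page per cluster — mask, cluster mean
spectrum, top-N selected m/z-images titled (m/z, r, q90) — plus the full
CSV; clusters with no significant ion get a page saying so.

## Classification

Two pixel groups (from ROI labels) are compared with an L2-regularized
linear SVM on standardized consensus-peak intensities under stratified
k-fold cross-validation (default 5 folds, seeded). A linear margin model
is used because its weights are directly readable as discriminative m/z
rankings, which is the scientific product here. Imbalance up to ten-fold
is fixed by decimation — every k-th spectrum of the larger group in
row-major pixel order, k = round(ratio), deterministic; beyond ten-fold
the call is refused with a pointer to sampling / cost-sensitive
approaches, which are out of scope. Accuracy bands: ≈50% on balanced
groups means nothing was learned and discriminative values are noise;
≥80% is good; 100% should not be expected from MALDI-imaging spectra
(annotation noise, tissue mixture, ion diffusion). The top discriminative
m/z values are always rendered as conditioned m/z-images — visual
inspection of their spatial pattern precedes any identification effort.
Single spectra, not ROI-averaged spectra, are classified.

## m/z-image conditioning

* **Hotspot suppression** clips intensities above the q-th quantile of
  the measured pixels (default 0.95, i.e. the brightest 5% are altered
  when values are distinct). Clipping rather than pixel deletion keeps
  the grid complete for downstream correlation. Monotone.
* **Histogram equalization** (scikit-image, measured pixels only) maps
  intensities to [0, 1] with an approximately uniform output CDF.
  Monotone.
* **Bilateral denoising** — spatial Gaussian × intensity-range Gaussian
  weights; neighbors across a step larger than `range_sigma` contribute
  negligibly, so edges survive while within-region multiplicative noise
  (which grows with intensity) is averaged down. Masked pixels never
  enter any window. This is a surrogate for published edge-preserving
  operators that are not specified at implementation level.
* The report pipeline applies them in the fixed order hotspot → equalize
  → denoise. Default colormap is jet (blue = low, red = high) for
  continuity with the field's figures; `viridis` is available via
  `viz.colormap` for perceptually uniform output.

## Synthetic data generator

The generator produces cubes with known ground truth so every downstream
stage can be scored exactly. Per pixel: spectrum = smooth baseline +
region-active Gaussian peaks (σ in Da) with isotope satellites at +1 Da
spacing decaying geometrically (factor 0.5, depth ≤ 3 — a qualitative
envelope, not an isotope model), each (pixel, peak) multiplied by an
independent log-normal factor with mean 1 and the specified CV (noise
multiplicative in intensity, the dominant MALDI-imaging noise mode), then
whole-spectrum scaling of hotspot pixels. Same seed → bit-identical cube.

The standard two-region fixture encodes the regime in which
spatially-aware methods visibly outperform naive clustering: weak
region-specific peaks (the colocalization targets), strong shared but
differentially expressed peaks whose intensity-proportional noise drives
scattered single-pixel misassignments at CV 0.3, and two matrix-like
everywhere-peaks. These contrast levels are a design choice of this
package — no quantitative noise model for MALDI-imaging is established —
and were fixed once when the fixture was designed. A thin-stripe fixture
(4-row stripe, CV 0.2) exposes the adaptive vs non-adaptive neighborhood
trade-off.

What the generator does **not** emulate: physical TOF peak shapes and
their m/z-dependent width, chemical baseline structure, detector
saturation, spatially correlated noise, and mass-calibration drift.
Passing tests therefore demonstrate algorithmic correctness under the
stated noise model, not performance on any real tissue dataset.

The two-group classification fixture places two pixel populations on
disjoint grid halves with five shared peaks and up to three
discriminative peaks whose group-B amplitude is (1 + effect) × group A's;
effect 0 makes the groups identical in distribution, effect 9 a ten-fold
ratio. Group sizes follow the requested imbalance exactly.

## Pipeline orchestration

Stages (`simulate`/`ingest` → `preprocess` → `peaks` → `segment` →
`interpret` → `classify` → `report`) each write artifacts plus a manifest
(hash of the relevant config sections + seed, package version, timing)
into the run directory, and are skipped on re-run when the manifest
matches, unless forced; a corrupt manifest produces a refusal naming the
fix. All randomness flows from the single config seed; equal configs give
byte-identical CSVs. Between stages the cube travels as a single HDF5
container, not imzML. Unknown config keys are rejected at load. Batch
mode isolates per-dataset failures and writes an index. Problem sizes in
the shipped tests and the acceptance script (grids of 10²–10⁴ pixels,
10²–10³ channels, 20 classification repetitions) were chosen as the
smallest at which the statistical contrasts of interest are stable.

## Known limitations

* Pearson p-values are nominal under spatial autocorrelation (above).
* The picker, denoiser and spatially-aware distance are documented
  surrogates, not reimplementations of any specific published operator.
* No 3D, FTICR/Orbitrap, SIMS or DESI support; no component methods
  beyond PCA; no molecular identification; vendor raw formats are not
  read.
* The hierarchical variant is inherently O(n²) memory; use the guard.
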