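# Methods

`hypercell` implements the computational half of a joint single-cell
imaging + sequencing workflow: label-free hyperspectral autofluorescence
images of cultured cells are segmented, summarized into per-cell optical
features, and linked to the same cells' transcriptomes. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Imaging model

A field of view is a 15-band stack, one frame per (excitation, emission)
wavelength pair. Most pixels are background, so the modal intensity of the
integer-rounded histogram of each channel estimates that channel's
background level. Normalization divides each channel by its mode and
rescales by a common factor (default 30 counts, a value near typical raw
background), putting all channels on a shared scale. Ties among modal bins
break toward the smallest intensity so the operation is deterministic on
camera-count data. Normalization is applied to whole fields, before any
cropping.

The default channel table carries the three wavelength pairs the
downstream analyses depend on — channel 3 (370/414 nm), channel 4
(343/451 nm, the free-NAD(P)H proxy), channel 13 (431/594 nm, the
membrane-ring channel) — and fills the remaining twelve channels with a
synthetic but instrument-plausible excitation ladder over the
NAD(P)H/flavin range. Users with a real instrument supply their own TSV.

## Segmentation and annuli

Cell masks normally come from an upstream pixel classifier and are
consumed as integer label images; `threshold_segment` (Otsu on a channel
mean, 8-connected components, minimum area 50 px) exists only so synthetic
fields are self-contained. It does not attempt to split touching cells;
the generator places cells apart.

The membrane-ring phenotype is quantified on two annuli derived from the
mask by the exact Euclidean distance transform to the nearest background
pixel center: the border annulus (depth ≤ t) and the adjacent inner
annulus (t < depth ≤ 2t), with t = 10 px. Euclidean distance was chosen
over erosion counts (Chebyshev) for isotropy; a `metric="chebyshev"`
switch is provided. The thickness is fixed in pixels regardless of cell
size. Cells thinner than one thickness have an empty inner annulus and an
explicitly *undefined* ring call — they are carried, never dropped.

## Per-cell features

* **Spectral fingerprint** — each channel is Gaussian-blurred (σ = 1 px,
  reflect boundary; σ unspecified upstream, exposed as a knob; σ = 0 gives
  the plain mean) and averaged over the mask, yielding a 15-vector.
* **Area** — the pixel count; µm² only when a pixel size is supplied
  (reported µm² values in the source material imply an unstated scale
  factor, so pixels are the ground truth here).
* **Eccentricity** — length/width − 1, with length and width the larger
  and smaller extents of the pixel cloud along its principal axes
  (bounding-box extents available via `axes="bbox"`); 0 for a round cell,
  unlike the standard ellipse eccentricity.
* **Intensity ratios** — ratios of fingerprint entries; the default (4, 2)
  pair contrasts the free-NAD(P)H channel with a blue-shifted one and is
  sensitive to the bound/free NAD(P)H balance.
* **Ring call** — log2(border mean / inner mean) in channel 13; a cell is
  *ringed* iff the log fold change strictly exceeds 0.4 (a cell exactly at
  the threshold is unringed), *undefined* if the inner annulus is empty or
  either mean is zero.

Summary percentages use floor truncation (`report_percent`), matching the
reporting convention of the workflow this package reproduces (60/174 →
34%).

## Spectral PCA and gating

PCA of the cells × 15 fingerprint matrix is computed by SVD after column
centering. Variance scaling is off by default (the fingerprints share
units); a `standardize` flag exists. Component signs are pinned by making
the largest-magnitude loading entry positive, so results are stable across
linear-algebra backends. Squared loadings attribute each component's
variance to channels and sum to one by orthonormality.

The number of components to keep is the position of the largest *relative*
drop ratio[j]/ratio[j+1] in the explained-variance spectrum. The relative
rule locates the elbow: (0.6, 0.3, 0.05) keeps two components because the
sixfold drop after the second dominates the twofold drop after the first.

Cells are gated into two spectral groups by thresholding a Gaussian KDE
(Scott bandwidth) of the (PC1, PC2) scores on a 256×256 grid with a 5%
margin. The two largest connected super-level regions define the groups;
group 1 is anchored to the cell with the smallest PC1 so the numbering is
reproducible. Cells outside both regions are assigned to the nearest
region boundary in score space (shape-aware; a centroid rule misassigns
fringe cells of elongated clusters). The default level, 0.18, is the
published operating point for the original data's score scale; because a
KDE density has units of 1/score², the right level changes with score
scale, so `relative=True` thresholds at a fraction of the peak density
instead (half-maximum gating, `level=0.5`, is what the synthetic recovery
conditions use). A straight-line gate was described as an alternative view
of the same boundary and is not implemented.

## Transcriptomics

Counts are features × cells integer matrices (pandas DataFrames); exon
level uses `gene:exonIndex` keys, 1-based ordinals from the upstream
flattened-exon counter (exon models are not re-derived from annotation).
QC computes totals, detected genes, and mitochondrial/ribosomal fractions
by symbol prefix (`MT-`, `RPS`/`RPL`, human defaults; overridable). A cell
is MT-high — a low-viability indicator — when its MT fraction exceeds
25%. Genes detected in fewer than 10 cells are removed; counts are then
CPM-normalized (column sums exactly 10⁶).

Differential expression between two cell groups uses the two-sample
Kolmogorov–Smirnov statistic D on cpm, signed by the direction of the
group-mean difference (medians optional); genes whose median cpm is zero
in either group are filtered before testing; q-values are
Benjamini–Hochberg over the tested genes (via statsmodels). Log2 fold
changes use group means with a pseudocount of 1 — medians can tie at the
filter boundary. p-values are exact (full enumeration of label
assignments) whenever C(n+m, n) ≤ 20 000, which covers every desk-scale
oracle case, and the asymptotic Kolmogorov distribution otherwise. The
monotone-transform invariance of D means testing cpm or log-cpm is
equivalent; only the sign convention could differ, and means on cpm were
chosen.

Exon usage divides each exon's count by its gene's per-cell total; it is
undefined (NaN) in cells where the gene has no reads and sums to one over
a gene's exons elsewhere.

## Feature–expression association

Spearman correlation (average ranks for ties, two-sided t-approximation
p-values) links a per-cell feature to each gene's cpm, restricted to
MT-low cells by default since MT-high cells carry an apoptotic signature.
Genes expressed in fewer than 10 of the selected cells are excluded. For
exon usage, the per-gene minimum and maximum correlation across exons and
their exon ordinals are reported; constant-usage exons (single-exon genes)
have undefined correlation and are excluded.

For box-plot style summaries, cells are sorted ascending by the feature
(ties broken by cell id) and cut into consecutive bins of 15, the last bin
holding the remainder — 117 cells give seven bins of 15 and one of 12.

The permutation test shuffles two-group labels (default statistic:
absolute difference of group means, the use case being the MT fraction of
ringed vs unringed cells) and reports the raw exceed count (strictly
greater) alongside the +1-corrected empirical p = (exceed+1)/(n+1). With a
constant value vector the observed statistic is 0 and the result is
flagged degenerate.

## Spectra matrices

Fluorescence detection at an (ex, em) pair is proportional to the product
of the excitation spectrum at ex and the emission spectrum at em, each
normalized to its own peak: I(ex, em) = (I_ex(ex)/I_ex(Ex0)) ×
(I_em(em)/I_em(Em0)). The matrix is rank 1 by construction, self-
normalizing under rescaling of either input curve, and attains 1 at
(Ex0, Em0). Curves are linearly interpolated between tabulated points with
no extrapolation; peak ties break toward the smallest wavelength. Channel
overlay evaluates the matrix bilinearly at each channel's wavelength pair
and ranks channels; the top channel is the proposed proxy for the
fluorophore (channel 4 for free NAD(P)H). The shipped NAD(P)H spectra are
synthetic single Gaussians with literature peak positions (free: ex 340,
em 460 nm; bound: ex 330, em 445 nm), not digitized published curves;
real analyses should load measured spectra from TSV.

## Synthetic data

`simulate_field` renders disk-shaped cells (radius 12–18 px, ≥ 2 px from
the field edge, non-overlapping) from two spectral populations on a flat
background of 30 counts with Gaussian noise (σ = 1). The default
populations share a 20-count lift and differ by +25 counts in channel 3
vs channel 13 — a deliberately well-separated contrast (≈ 8 cluster
standard deviations given the 5% per-cell brightness jitter) emulating
distinct metabolic states. For ringed cells (34% by default, matching the
observed cohort) every pixel within 10 px of the boundary in channel 13
is multiplied by 2^(planted log2 fold change), using the same distance
transform as the classifier. Cells are labeled in raster order of their
first row-major pixel, exactly the fallback segmenter's rule, so
generator truth and segmentation output align by construction.

`simulate_counts` draws negative-binomial marginals (dispersion size 3;
null-gene means log-uniform on 2–150) and couples planted genes' ranks to
a per-cell feature through a Gaussian copula with latent correlation
r = 2 sin(πρ/6), which induces Spearman ρ exactly for continuous
marginals. Planted genes draw well-expressed means (50–200) so NB rank
ties do not attenuate the coupling; the residual attenuation from
discreteness and cpm library-size variation is ≲ 0.02 at ρ = 0.5.
Mitochondrial reads are layered on top of the nuclear genes as a Poisson
total targeting each cell's drawn MT fraction (MT-low 2–20%, MT-high
30–60%), split over the 13 human MT protein-coding symbols. Exon counts
split each exon gene's reads multinomially; planted gradients shift the
exon logits linearly along the feature's rank. Group-wise mean shifts
(2^fc) plant differential expression for ring-marker demos. All
randomness flows from one seed through named substreams, so partial
re-runs are stable.

The generators emulate: disk-like cells, flat noisy background, membrane
rings, two separable spectral populations, NB overdispersion, planted
rank correlations, exon-usage gradients, MT-fraction structure. They do
not emulate: realistic optics (PSF, photobleaching, uneven illumination),
touching cells or doublets, batch effects, dropout beyond NB zeros, gene–
gene correlation, or realistic transcriptome breadth. Passing recovery
tests therefore demonstrates correctness of the estimators under their
stated models, not robustness to every artifact of real micrographs or
libraries.

## Problem sizes

The shipped conditions are desk-scale by choice: imaging fields of
320 px / 20 cells (10 fields ≈ 200 cells for ring recovery; 30 fields for
gating recovery over 10 replicates), cohorts of 117 cells for correlation
recovery (50 genes per planted ρ ∈ {−0.5, 0, 0.5}), 500 null genes at
50 vs 50 cells for KS calibration, 200 runs of a 1000-shuffle (tests:
200-shuffle) permutation null. The demo presets use one 800-px field of
120 cells, comparable to the original cohort's first batch.

## Known limitations

* The fallback segmenter requires well-separated bright cells and is not
  a general-purpose cell segmenter.
* The KDE gate assumes exactly two groups; more structure requires a
  different method (out of scope).
* Asymptotic KS p-values are conservative in the presence of heavy ties
  (many zero counts); the median filter removes the worst cases.
* The eccentricity definition (length/width − 1) is not the conventional
  ellipse eccentricity; comparisons across tools must account for this.
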