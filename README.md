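# hypercell

Linking what a cell *looks like* to what it *expresses*: `hypercell` is a
Python library and CLI for joint analysis of 15-channel hyperspectral
autofluorescence images and same-cell transcriptomes. It is aimed at
groups running label-free imaging of cultured cells (e.g. MCF-7) followed
by full-length single-cell RNA-seq on the very cells that were imaged,
and at anyone who wants a tested, synthetic-data-backed reference
implementation of that analysis stack.

## What it computes

* **Background normalization** — each channel is divided by its modal
  (background) intensity and rescaled: `out = in / mode(in) × 30`.
* **Per-cell features** — the spectral fingerprint (15-vector of mean
  blurred intensities over the mask), area in pixels, eccentricity
  `y/x − 1` (principal-axis length over width), and inter-channel
  intensity ratios such as ch4/ch2.
* **Membrane-ring detection** — the mask is split by the Euclidean
  distance transform into a 10-px border annulus and the adjacent 10-px
  inner annulus; a cell is *ringed* iff
  `log2(mean_border / mean_inner) > 0.4` in channel 13.
* **Spectral PCA + KDE gating** — SVD-based PCA of the fingerprints,
  squared-loading channel attribution, variance-elbow component
  selection, and gating of the (PC1, PC2) plane into two groups by
  thresholding a 2-D Gaussian KDE (default level 0.18; scale-free
  half-maximum mode available).
* **Transcriptomics** — per-cell QC (MT-high ⇔ mitochondrial fraction
  > 25%), the <10-cells gene filter, CPM normalization, and
  differential expression by the **signed Kolmogorov–Smirnov statistic**
  `D·sign(mean_a − mean_b)` with zero-median filtering and
  Benjamini–Hochberg correction; exon-level usage fractions
  `counts[g:e, c] / Σ_e counts[g:e, c]`.
* **Feature–expression association** — Spearman correlation of any
  imaging feature with expression or exon usage in MT-low cells, 15-cell
  binned summaries, per-gene exon-correlation extremes, and label-shuffle
  permutation tests (1000 shuffles).
* **Spectra matrices** — excitation × emission grids
  `I(ex, em) = (I_ex(ex)/I_ex(Ex0)) · (I_em(em)/I_em(Em0))` with channel
  overlay to pick the proxy channel for a fluorophore such as free
  NAD(P)H.
* **Synthetic data** — seeded generators for hyperspectral fields (disk
  cells, planted rings, two spectral populations) and negative-binomial
  count matrices with Gaussian-copula-planted Spearman correlations and
  exon-usage gradients, so every stage has a recoverable ground truth.

## Worked example

```python
import numpy as np
import hypercell as hc

stack, labels, truth = hc.simulate_field(hc.ImageSimSpec(seed=7))
ns = hc.normalize_stack(stack)                 # background -> 30 counts
cells = hc.extract_cells(labels)
ft = hc.compute_features(ns, cells)            # one row per cell

print(ft[["area_px", "eccentricity", "ring_log2fc", "ring_call"]].head())
n_ringed = int(ft["ring_call"].eq("ringed").sum())
print(f"{n_ringed}/{len(ft)} ringed ({hc.report_percent(n_ringed, len(ft))}%)")

res = hc.fit_spectral_pca(ft[[f"mean_ch{i:02d}" for i in range(1, 16)]].to_numpy())
print("explained variance:", np.round(res.explained_variance_ratio[:3], 3))

overlay = hc.overlay_channels(
    hc.build_spectra_matrix(hc.free_nadh_spectrum()), hc.default_channel_table()
)
print("free NAD(P)H proxy channel:", overlay.index[0])
```

prints

```
         area_px  eccentricity  ring_log2fc ring_call
cell_id
1            617      0.009284    -0.004781  unringed
2            534      0.000000     0.999714    ringed
3            532      0.027462     0.997071    ringed
4            906      0.005665    -0.001094  unringed
5            617      0.001245     0.991088    ringed
10/20 ringed (50%)
explained variance: [0.886 0.108 0.006]
free NAD(P)H proxy channel: 4
```

The generator planted a ring contrast of one log2 unit in half the cells;
the classifier recovers every planted flag (`ring_log2fc ≈ 1` for ringed
cells, ≈ 0 otherwise). PCA concentrates the fingerprint variance on two
components — the two planted spectral populations plus common-mode
brightness — and the spectra-matrix overlay identifies channel 4
(343/451 nm) as the best proxy for free NAD(P)H.

From the shell, the same pipeline runs as:

```sh
hypercell simulate --preset ring-demo --seed 3 --out demo/
hypercell run --config demo/config.yaml --analysis ring-de --out demo/out/
```

which writes the feature table, QC, the signed-KS differential-expression
table between ringed and unringed cells, the MT-fraction permutation
test, and a provenance log (`run_log.json`, effective `config.yaml`).

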