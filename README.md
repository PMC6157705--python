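# saxseg

Model-free classification and segmentation of scanning SAXS/WAXS maps.

Scanning small- and wide-angle X-ray scattering rasters a focused beam
over a sample and records one azimuthally integrated curve I(q) per scan
pixel. For heterogeneous samples — rocks, tissues, composites — every
curve is a mixture of the phases along the beam path, and fitting each
curve with a scattering model is rarely possible. `saxseg` instead
classifies curves by shape similarity and segments the scan map without
any model of the sample:

1. **Normalize** each curve by its mean intensity over the measured q
   range (classification should respond to shape, not thickness), then
   **resample** onto a logarithmic q grid, reducing the number of q
   values tenfold and damping counting noise: the r x c matrix **M1**.
2. **Extract features**: only the intensities at each curve's inflection
   points — the q positions where the first or second derivative of I
   with respect to log q vanishes — are kept. Bragg peaks and slope
   changes are exactly such points. Per-curve detections are pooled into
   a shared column set and zero-filled: the sparse r x d matrix **M2**,
   d < c.
3. **Reduce** M2 by PCA; the component count m is the smallest number of
   components explaining ≥ 95% of the variance (the L-curve knee is
   reported as a diagnostic).
4. **Cluster** the m-dimensional scores by k-means, choosing the cluster
   count n in 2..8 as the maximizer of the mean silhouette
   s = (b − a)/max(a, b) under the Euclidean metric.
5. **Segment** the scan map by cluster label and extract one
   representative signal S_i per cluster: either the member nearest its
   centroid, or the mean of the 10% of members with the largest summed
   distance to all centroids (the least mixture-contaminated points).
6. **Correlate** every pixel's curve with each S_i (Pearson's ρ),
   threshold each map at its median, and compose up to three maps into
   an RGB image of phase distribution.

A synthetic phantom generator (Gaussian Bragg lines on power-law +
constant backgrounds, linear phase mixing, Poisson counting noise)
provides ground truth so the whole chain is testable without beamline
data.

## Worked example

```sh
$ saxseg report --seed 0 --out phantom_demo
bundle written to phantom_demo
n  mean silhouette
2  0.6115
3  0.8448
4  0.9901 *
5  0.9806
6  0.8292
7  0.7144
8  0.6025
selected n = 4 clusters
segmentation accuracy on non-mixed pixels: 100.0%
best representative-vs-phase correlation per cluster: 1.000, 1.000, 1.000, 1.000
```

The demo generates the reference phantom — a 32x32 scan of four mineral-
like phases arranged in quadrants, 1000-point q grid over 1–30 nm⁻¹,
expected 1e5 photons per curve — and runs the full pipeline. The
silhouette table shows a clear maximum at n = 4, matching the number of
phases in the phantom; the resulting label map reproduces the quadrant
ground truth exactly, and each furthest-10% representative signal is
essentially identical (ρ ≈ 1.000) to one true phase spectrum. The bundle
directory contains the working matrices, the PCA L-curve and silhouette
tables, the label map (PNG/TIFF + CSV sidecar), the representative-signal
table, per-cluster correlation maps, the RGB composite, and a manifest
with the seed and configuration hash.

The same pipeline runs on real data from a curve-stack file:

```sh
saxseg simulate --seed 1 --out phantom       # or bring your own stack
saxseg run config.txt                        # flat key = value config
```

Library use mirrors the CLI: `saxseg.segment_curves(values, q, grid)`
returns every stage's output as arrays.

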