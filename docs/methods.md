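# Methods

## The classification model

The input to the analysis is a stack of azimuthally integrated
scattering curves I(q), one per scan pixel, on a single shared q grid.
The method assumes that phases along the beam path contribute *additively*
to the measured intensity (incoherent mixing) and that phase identity is
encoded in the *shape* of the curve — the positions and relative heights
of Bragg peaks and the exponents of diffuse power-law scattering — not
in its magnitude, which varies with thickness and flux.

The chain is:

    normalize (row mean = 1)  ->  log-resample (c = ceil(c_raw/10))
    ->  inflection features (r x d, zero-filled)  ->  PCA (m components)
    ->  k-means over n in 2..8, silhouette-selected
    ->  label map, representative signals, Pearson correlation maps

Normalization precedes resampling: the per-curve mean is taken over the
measured range as acquired. Resampling uses bin *averaging* (not
decimation) on edges uniform in log q; bin centers are the geometric
mean of their edges, so the working grid remains log-uniform and
derivatives with respect to log q can use a constant spacing. Empty bins
(possible only on sparse irregular grids) are filled by linear
interpolation from neighboring bins and logged.

## Inflection-point features

Features are the q positions where the first or second derivative of
the (normalized) intensity with respect to log q changes sign.
Derivatives are estimated by Savitzky–Golay local polynomial fits
(default window 7 bins, order 2); taking them against log q means slope
features track power-law exponents, and a pure power law — a straight
line in log-log whose linear-intensity derivatives never change sign —
correctly yields no features.

Per-curve detections are pooled: the feature grid q_d is the union of
all detected bins in increasing q order, and each row of M2 holds its
own intensity at the bins it detected, zero elsewhere. Values are drawn
verbatim from M1; there is no re-interpolation. Rows with no detections
stay all-zero but are retained, so row index always maps to scan
position.

**Noise guard.** A sign change is accepted only if both same-sign lobes
flanking the zero crossing reach `prominence_floor` (default 0.2) times
the row's maximum derivative magnitude at their extremum. Judging lobes
rather than the two samples adjacent to the crossing makes the guard
independent of sampling density: the samples next to a steep crossing
shrink with bin width, but the lobe extrema do not. A noise blip inside
a large lobe creates two crossings each flanked by a tiny lobe, so both
are rejected and the lobe stays whole. The defaults were calibrated on
the reference phantom: with Poisson noise at 1e5 counts per curve they
keep the pooled feature count well below the working grid size
(d ≈ 32 of c = 100) while preserving every noise-free feature of the
analytic test curves; window 5 / floor 0.05 saturate the union (d = c)
under the same noise.

One consequence worth knowing: a local *minimum* between two peaks is a
first-derivative zero and is detected as a feature. This is deliberate —
valleys between Bragg peaks are structural information.

## Component count and cluster count

PCA is computed with a full SVD; m is the smallest component count whose
cumulative explained variance reaches `variance_threshold` (default
0.95). The geometric knee of the L-curve (maximum distance to the chord
of the cumulative curve) is computed and reported as a diagnostic; when
the two disagree the threshold rule wins and the discrepancy is logged,
because the threshold rule is unambiguous and monotone in the threshold.

k-means (greedy k-means++ seeding, 20 restarts, best inertia kept,
max 300 iterations) is run for every candidate n in 2..8; the mean
silhouette of each resulting partition, computed with the Euclidean
metric on the m-dimensional PC scores, selects n. Singleton clusters
score 0, as does the degenerate a = b = 0 case; ties between candidates
resolve toward smaller n (parsimony). All randomness derives from one
top-level seed (per-candidate seeds are fixed functions of it), so a
run is reproducible bit for bit from its manifest.

## Representative signals

Two extraction rules per cluster:

- `centroid_nearest` — the single member curve whose PC-score distance
  to its own centroid is minimal (ties to the lowest row index).
- `furthest_mean` — the unweighted mean of the ceil(10%) of members
  with the largest *summed* Euclidean distance to all n centroids.
  Summing over all centroids (rather than the own centroid only, which
  is available as `distance_rule="own"`) pushes the selection away from
  every cluster core at once, i.e. away from inter-cluster interfaces
  where signals mix.

Representatives are reported on the normalized working grid; they are
shapes, not absolute intensities.

**Limitation.** The interface-avoidance rationale assumes mixed signals
lie *between* cluster cores in score space. Under the zero-filled union
feature matrix this is not guaranteed: a mixed pixel can detect the
union of two phases' inflection bins and thereby acquire nonzero
coordinates no pure pixel has, moving it away from *all* centroids.
On phantoms with wide cross-fade interfaces the furthest-10% selection
of one cluster can therefore include interface pixels and be less pure
than the cluster median — the own-centroid rule is strictly worse in
the same situation. With hard phase boundaries the rule behaves as
intended and each furthest-mean signal matches exactly one true phase
spectrum (ρ > 0.999, bijectively).

## Correlation maps

Each pixel's working curve is correlated (Pearson, sample n−1
convention) with each representative signal. Zero-variance curves and
rows excluded upstream yield NaN — flagged missing, deliberately not 0.
Each cluster's map is thresholded at its own median over finite pixels
(entries strictly below the median are zeroed; the median itself
survives); the per-map reading of "the image median" was chosen over a
single global median across all maps — also available via config —
because maps of different clusters have incommensurate correlation
scales. RGB composition assigns three thresholded maps to channels,
clips negatives, and normalizes each channel by its own maximum so
spatial structure survives weak absolute correlations.

## The synthetic phantom

A phase is a sum of Gaussian lines A·exp(−(q−μ)²/2σ²) on a power-law
B·q^(−p) plus constant F; all four parameters are per phase. The
phantom mixes P ≥ 2 phases linearly with per-pixel weights summing to 1,
then draws independent Poisson counts per q bin with the clean curve as
mean, scaled so the expected total per curve equals `counts_scale`.
Weight maps are Voronoi cells of P site points with an optional linear
cross-fade band of `mix_width` pixels at cell boundaries; ground-truth
labels are the argmax weights, and pixels where no phase reaches weight
0.5 are flagged mixed and excluded from accuracy scoring.

The reference phantom (used by the demo, the tests and the acceptance
script) is a 32x32 scan, 1000-point log-spaced q grid over 1–30 nm⁻¹,
four phases on quadrant sites with hard boundaries, and 1e5 expected
counts per curve — a realistic per-pixel dose for a counting detector at
sub-second exposures. Three phases are peak-rich with distinct Bragg
lines, one is diffuse and power-law dominated; peak widths grow with q
so every line survives tenfold log rebinning, and amplitudes are chosen
so normalized shapes are well separated (pairwise |ρ| ≤ 0.5). An early
draft with background-dominated shapes produced phase pairs with
ρ = 0.99 after normalization — indistinguishable in principle by any
shape-based method — which is a statement about degenerate inputs, not
about the classifier.

What the phantom does *not* emulate: anisotropic (azimuth-dependent)
scattering, nonlinear inter-phase contributions, instrument geometry
and smearing, detector artifacts, and spatially correlated backgrounds.
Passing tests therefore demonstrate the correctness of the chain under
additive mixing and Poisson noise, not robustness to those effects.

## Numerical conventions

- q grids must be strictly increasing and positive; curves on differing
  grids are rejected, never silently interpolated.
- Pixel indices are 0-based; cluster labels 1-based with 0 meaning
  unassigned/excluded. Raster order is row-major by default; `snake`
  reverses odd rows.
- Background subtraction clips negative residuals to zero (intensities
  are counts) and logs the clip count; curves emptied by subtraction
  and all-zero curves are excluded from clustering but kept in maps as
  label 0.
- Mean silhouette is computed on all points (no subsampling) from the
  full pairwise distance matrix.
- Problem sizes in the test and acceptance runs (32x32 scans, 1000-point
  raw grids, 20 replicates) are chosen so the complete validation runs
  in about a minute on one CPU while keeping ≥ 250 pixels per phase.
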