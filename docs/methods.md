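# Methods

`cellpattern` quantifies how cultured cells organize on a substrate from
the positions of their nuclei. Two complementary analyses are provided: a
radially averaged two-point autocorrelation of the binary nuclei image,
which measures typical object (cell-agglomeration) sizes and spacings, and
a cluster-number inference stack over nuclei coordinates, which counts and
characterizes discrete cell clusters. A synthetic point-pattern generator
supplies controlled inputs for both.

## Coordinate and raster conventions

Coordinates are continuous micrometres, origin at the top-left corner of
the field, x rightward, y downward. A raster pixel (row i, column j) has
its centre at ((j+0.5)·s, (i+0.5)·s) for pixel size s. All modules share
this single convention; rasterization stamps a point as a filled disk by a
pixel-centre-in-disk test, and detection converts component centroids back
with the same convention, so a lossless round trip is possible whenever
disks do not overlap.

## Synthetic point patterns

* **Homogeneous Poisson** (`generate_homogeneous`): complete spatial
  randomness; the count is Poisson with mean intensity × area and
  positions are uniform. The reference intensity used throughout the test
  fixtures is 130 cells/mm², a typical seeding density for substrate
  cultures, on fields from 4 mm² (desk-scale runs) up to the 22 mm²
  substrate scale.
* **Thomas process** (`generate_clustered`): Poisson parents with
  Poisson-distributed offspring displaced by an isotropic Gaussian
  (spread `spread_sd` µm). Children falling outside the field are
  discarded, not reflected; with `spread_sd` much smaller than the field
  the resulting edge loss of expected count is below a few percent. This
  is a generic stand-in for neuron-like agglomerated growth — it is not
  calibrated to any measured culture, and real agglomerations are neither
  Gaussian nor independent.
* **Planted blobs** (`generate_blobs`, `random_separated_blobs`): exactly
  `n_per_blob` Gaussian points per centre with ground-truth labels. The
  frozen fixture **CLUST-A** (field 2000×2000 µm, pixel 2 µm, four centres
  at (400,400), (400,1600), (1600,400), (1600,1600), 200 points each,
  sd = 60 µm, seed 42) has centres 20 standard deviations apart, so the
  planted partition is the unambiguous optimum; it is the package's
  worked example for four-cluster recovery. Note that its *points* are
  nevertheless dense within blobs (nearest-neighbour distances well below
  1 µm occur), so its rasterized nuclei disks overlap; CLUST-A exercises
  clustering and autocorrelation, while detection round-trip exactness is
  demonstrated on sparse, provably disjoint fixtures.

What the generators do not emulate: fluorescence textures, uneven
illumination, nucleus shape/size variation, touching-nuclei morphology,
or density-dependent growth. Passing tests therefore validate the
numerics and the inference logic, not robustness to microscopy artifacts.

## Nuclei detection

Grayscale images in [0,1] are thresholded (Otsu by default, since the
upstream acquisition pipeline's exact method is generally unknown; a fixed
threshold is available for reproducibility) and segmented by connected
components (8-connectivity default, the particle-analysis convention).
Components are filtered by area in µm² and reduced to centroids. Particles
touching the border are kept by default — whole-substrate tiling means
discarding them would bias counts — with an `exclude_border` flag.
Touching nuclei merge into one particle: there is no watershed splitting,
a stated limitation, so quantitative count tests use non-overlapping
fixtures.

## Radially averaged two-point autocorrelation

For a binary image I with fill fraction p, the raw lag correlation
A(Δ) = Σₓ I(x)I(x+Δ) is computed as a full linear correlation via FFT
(`scipy.signal.fftconvolve`), which internally zero-pads to at least
double size so the FFT's periodic wrap-around never mixes opposite image
edges. Dividing by the per-lag count of valid pixel pairs — the same
correlation applied to an all-ones support mask — corrects for the finite
image: Â(Δ) is the probability that two in-image pixels at lag Δ are both
foreground. Both numerators and denominators are integer counts and are
rounded to kill FFT noise, which is why the FFT path agrees with the
brute-force pair-counting oracle to below 1e-9.

Per-lag values are normalized to the covariance form
S2 = (Â − p²)/(p − p²), which anchors S2(0) = 1 exactly (at lag zero
Â = p) and S2 → 0 for spatially uncorrelated images. Radial averaging
uses annuli [k, k+1) pixels: the unweighted mean of the normalized values
over all integer lags whose Euclidean length falls in the bin, with empty
bins (none occur below half the image side) filled by linear
interpolation. `max_radius` defaults to a quarter of the shorter image
side and may not exceed half of it.

**Features.** On the moving-average-smoothed curve (window 5 bins,
odd-sized), the first interior local minimum with prominence ≥ 0.01 marks
the typical object size and the first subsequent maximum the typical
object spacing; the curve is *undulating* when both exist (homogeneous
objects of uniform size). The *correlation length* is the smallest radius
where the forward-difference magnitude drops below `slope_fraction`
(default 0.05) times the maximum magnitude of the initial decline — the
bend from steep decay to a near-constant regime. The prominence and slope
thresholds are operational stand-ins for reading a curve by eye; on
two-scale synthetic images (isolated disks inside loose clusters) the
rule reports the inner (disk) scale, and only contiguous agglomerations
— nuclei packed densely enough that their disks merge — move the bend to
the agglomeration scale, which is the regime the method is meant for.

## Cluster-number inference

**K-means.** Lloyd's algorithm on the (x, y) coordinates: initial centres
drawn uniformly without replacement from the data points, assignment by
Euclidean distance, centroid update by cluster means, until assignments
stabilize or the maximum centre movement falls below `tol` (1e-6 µm; cap
300 iterations). An empty cluster is re-seeded at the point farthest from
its assigned centroid. The best of `n_restarts` (default 10) runs by total
within-cluster variation totW is kept. totW is asserted non-increasing
across iterations on every run. All randomness flows from one seed through
`numpy.random.SeedSequence` spawning, so the full pipeline is reproducible.

**Elbow.** totW(k) for k = 1..kmax, both axes normalized to [0,1], and
the bend located as the argmax of discrete (finite-difference) curvature
of the polyline. A curve whose largest curvature is less than half the
curvature total has no dominating bend (e.g., a lone Gaussian blob, where
totW decays smoothly like 1/k) and is flagged low-confidence; a
non-decreasing totW curve is flagged pathological with k = 1.

**Gap statistic.** For each of B (default 50) reference sets, n points
are drawn uniformly over the data's axis-aligned bounding box (the simple
reference choice; no PCA alignment) and clustered for every k.
Gap(k) = mean_b log totW_ref,b(k) − log totW_data(k) with natural logs,
sd(k) is the standard deviation over the B replicates, and
s(k) = √(1 + 1/B)·sd(k). The selected K is the smallest k with
Gap(k) ≥ Gap(k+1) − s(k+1), falling back to kmax if the rule never fires.
Reference sets enter only through the mean and spread of log totW across
B replicates, so they use fewer K-means restarts (default 3) than the
data fit; the extra per-replicate noise is absorbed into sd(k). On the
CLUST-A fixture the selection (K = 4) is stable across seeds at this
setting.

**Silhouette.** For every cell, y(i) is the mean distance to the other
members of its cluster (excluding itself), x(i) the smallest mean
distance to the cells of any other cluster, and
SilCoef(i) = (x−y)/max(x, y) ∈ [−1, 1]; cells in singleton clusters get
coefficient 0 (the usual convention). The mean width over cells is the
clustering-quality score; −1/0/+1 are interpretive anchors (wrong
cluster / on the boundary / well placed), not the only attainable values.

**Selection with quality control** (`select_k`). The gap statistic
proposes a candidate K. If its mean silhouette width reaches the quality
threshold (0.35), it is accepted. Otherwise the mean width is evaluated
for every k in 2..kmax — a deterministic exhaustive search rather than an
unspecified iteration order — and the highest-width k among those
reaching the threshold is selected; if none reaches it, the max-width k
is returned flagged `unreliable`. Note a caveat established while
validating the control: K-means partitions of *uniform* planar data have
mean silhouette widths of about 0.36–0.41 for k = 2..10 (confirmed
independently with scikit-learn), i.e., above 0.35, so a homogeneous
pattern is typically *not* flagged by the threshold alone; the flag is
effective against patterns whose best partition is genuinely poor, and
the gap statistic (Gap ≈ 0 at all k for uniform data) is the more
reliable homogeneity indicator.

**Per-cluster metrics.** Cluster area is the covariance ellipse at a
configurable coverage (default 0.95): area = π·q·√(det Σ) with q the
chi-square quantile at that coverage with 2 degrees of freedom and Σ the
member covariance; density is members per ellipse area in cells/mm², and
members whose squared Mahalanobis distance exceeds q are flagged
outliers (≈ 1 − coverage of the members for Gaussian clusters). Clusters
with fewer than 3 members, or collinear ones, have undefined area and
density (NaN, with a warning).

## Pipeline

`run(config)` executes detection (images) or direct loading (CSV point
lists; rasterized with a configurable nucleus radius for the
autocorrelation branch), then both analysis branches, writing per-sample
CSVs and one JSON report carrying every number plus provenance (config
hash excluding the output path, seed, package version). A failing stage
is recorded per sample without aborting the batch. `compare_conditions`
tabulates group means ± standard error of the mean for cell count,
correlation length and in-cluster density; it deliberately performs no
hypothesis tests. The pipeline takes one image per sample; stitching of
tiled acquisitions is out of scope.

## Problem sizes in the test suite

The suite favours fixtures small enough to iterate on: oracle-equivalence
checks use images up to 16×16 (100 random draws), exactness checks use
20-point instances (100 draws), the no-correlation anchor uses one
1024×1024 image, recovery experiments use 50 patterns of 300–900 points
on 2000×2000 µm fields with kmax 6–8, and the homogeneous control uses
130 cells/mm² on a 4 mm² field (~520 cells). Monte-Carlo means use
200–10,000 seeds depending on the cost of a draw.

## Known limitations

* No watershed splitting of merged nuclei; counts on overlapping disks
  are biased low by construction.
* The correlation-length rule reports the innermost scale of multi-scale
  images (see above).
* Thomas-process parameters are illustrative, not fitted to real
  cultures.
* Cluster areas assume elliptical (Gaussian-like) clusters; irregular
  agglomerations will be summarized coarsely.
* The 0.35 silhouette threshold does not reject uniform spatial
  randomness by itself (see selection section).
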