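# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind the `mitofish` pipelines. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and unit conventions

All physical coordinates are nanometers. Images are row-major with the
origin at the top-left corner; the center of pixel (i, j) is at
x = (j + 0.5)·pitch, y = (i + 0.5)·pitch. Pixel indices are never written
to files. Gaussian widths are interchangeably given as FWHM or σ with
FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ.

## STED raster pipeline

The raster analysis is a fixed chain:

1. **Smoothing** — isotropic Gaussian, FWHM 25 nm, reflective boundaries
   (conserves total intensity to machine precision; verified to 1e−6
   relative in tests).
2. **Background subtraction** — the same image smoothed at FWHM 210 nm is
   subtracted (a difference of Gaussians). Negative values are retained.
3. **Spot calling** — strict 8-neighbour local maxima with value ≥ 3
   counts, at least 100 nm (= ⌈100/pitch⌉ pixels) from every edge.
   *Threshold reading:* "at least 3 counts" is implemented inclusively
   (≥ 3). *Plateau tie-break:* a connected plateau of equal maximal values
   that is strictly above all surrounding pixels contributes exactly one
   spot at its rounded pixel centroid; adjacent candidate pixels
   necessarily share one value, so plateaus are well defined. This
   tie-break is a package decision — raster analyses rarely specify it —
   and is regression-tested.
4. **Mitochondrial mask** — (1) union of Euclidean lattice disks of radius
   6 px around the maxima (a single disk covers exactly 113 px, so an
   isolated spot can never seed a mask given the 200 px component
   threshold); (2) remove 8-connected components < 200 px; (3) convolve
   the 0/1 mask with a 5×5 box; (4) keep values > 12.5 (majority vote of
   the 25-pixel neighbourhood); (5) fill 4-connected holes < 200 px that
   do not touch the border. The order matters: thresholding a 0/1 mask at
   12.5 *before* the box convolution annihilates it (regression-tested
   counterexample). Connectivity pairing (8 for foreground components,
   4 for holes) is the conventional dual and is fixed in code.
   *Seeding channels:* which channel's maxima seed the mask is
   experiment-dependent; the default is the union of all provided
   channels, configurable to a named subset. Mask seeding uses the
   thresholded spots (≥ 3 counts), not all local maxima.
5. **Quantities** — densities are reported per µm² (primary) and per pixel
   (raw); the mRNA-to-nucleoid ratio divides in-mask mRNA spots by in-mask
   mtDNA spots; minimum pairwise distances between two channels pool both
   directions (a→b and b→a) by default, with a per-direction flag.
6. **Spot FWHM** — least-squares fit of an isotropic 2D Gaussian plus
   constant offset in a 7×7 px window (a decision; the measurement
   procedure for spot sizes is not standardized). Fits that fail to
   converge, exceed the window, or sit too close to the edge are flagged
   NaN and excluded from summaries.
7. **Distance summaries** — median and quartiles via the
   linear-interpolation order-statistic rule (`numpy.percentile`);
   Gaussian-kernel KDE with the 1D Scott bandwidth h = σ̂·n^(−1/5)
   (σ̂ = sample SD, ddof 1). Samples with n < 2 or zero spread carry no
   KDE and emit a warning.

## MINFLUX pipeline

* **Alignment** is translation-only: sequential rounds on one stage differ
  by drift, not rotation or scale. Each dataset is shifted by the
  difference between its mean shared-bead position and the reference
  dataset's (the first by default). Bead tracks are averaged per bead
  before averaging across beads, so uneven track lengths cannot bias the
  centroid. Time stamps are carried through but unused; no within-round
  drift model is applied.
* **Event combination** keeps traces with *more than four* localizations
  (n = 4 dropped, n = 5 kept; boundary tested), averages per axis, and
  reports per-axis standard errors SD/√n. The radial precision pools x
  and y as s_r = √((sₓ²+s_y²)/2), keeping s_r commensurate with a
  single-axis value; the quadrature sum √(sₓ²+s_y²) is available via
  `s_r_convention="quadrature"`.
* **Precision filter**: per dataset, the axis of {s_r, s_z} with the
  larger mean is the worst axis; events whose precision value on that axis
  exceeds twice the *pre-filter* mean are discarded in a single pass. The
  underlying prose ("a precision below two times its mean") is ambiguous —
  precision-as-quality versus precision-as-σ; discarding σ > 2·mean is the
  reading implemented here. The filter runs before DBSCAN (processing
  order), and a second application can remove more points because the mean
  is re-estimated — the single-pass semantics are regression-tested.
* **DBSCAN** (ε = 120 nm, min 8 points including the query point) is
  implemented from the original definition — core points, density
  reachability, stack-based expansion — with a KD-tree for neighbourhood
  queries. Tests require label-for-label equality with an O(n²)
  from-the-definition reference on random fixtures and partition
  equivalence with scikit-learn's implementation (border-point ties are
  implementation-defined and excluded from the cross-check).
* **Cross-dataset distances** are 3D nearest-neighbour distances per
  dataset pair, both directions pooled; pairs with a side emptied by
  filtering are skipped with a warning.
* **Sphere export** writes one record per combined localization with a
  10 nm default diameter, as CSV (exact float round-trip) and ASCII PLY.

## STED emulation

3D points are flattened by dropping one axis (z by default), binned onto a
20 nm grid and convolved with a normalized 40 nm FWHM Gaussian. Binning
before convolution, and the 20 nm pitch matching real rasters, are package
decisions. Each point contributes unit weight so the image total equals
the point count (conservation holds to 1e−6 with reflective convolution;
the grid is padded by 3 FWHM so nothing clips). The emulation obeys the
Gaussian broadening law: a point cloud of RMS extent s yields a fitted
FWHM of √(40² + (2.3548·s)²), verified within 10% on synthetic clouds. No
noise is added to emulated images.

## Synthetic scenes

The generator defines the regimes in which the pipelines are validated.

**STED scenes.** Tubules are smoothed 2D random walks (step 100 nm,
turning SD 0.35 rad, half-width 150 nm — a few-hundred-nm tubule diameter)
kept clear of the raster border so spot Gaussians are not clipped. Spots
are placed uniformly along arc length with uniform lateral jitter within
the half-width; per-species counts are Poisson with density 1.5 spots per
µm of centerline by default (spot density per µm is a free parameter of
the generator, not a published value). Images are Poisson draws of
background (0.5 photons/px) plus Gaussian peaks (FWHM 85 nm, matching the
observed bDNA spot size; peak amplitude 50 photons), sampled at pixel
centers; expected totals obey amplitude·2πσ²/pitch² per spot, verified to
1% over 50 seeds. An optional minimum same-species separation (rejection
sampling) creates the well-separated regime used for recall/precision
tests. Scenes whose raster cannot contain a tubule raise an error.

**MINFLUX scenes.** Each dataset (species/round) has mRNAs placed
uniformly in a 1.5×1.5×0.5 µm ROI, each either compact (docking sites in
a 15 nm RMS cloud) or elongated (sites along a gently curved 100–250 nm
contour), with 3–8 docking sites and Poisson(3) binding events per site.
Trace length is 1 + Poisson(7) — median 8 — so both rejected (≤ 4) and
kept (> 4) traces occur. Raw localizations scatter around their site with
per-axis Gaussian noise σ = (7.92, 7.92, 3.11) nm, chosen analytically as
target·√8 so that combined-event medians land in the published precision
regime (s_r ≈ 2.8 nm, s_z ≈ 1.1 nm) at the median trace length. Because
the sample SD of small traces is biased low (chi distribution), recovered
medians sit a few percent below the nominal targets — within the 10%
recovery tolerance; the axial median is affected slightly more than the
radial one, which averages two axes. Background is emitted both as
single-localization traces (removed by event combination) and as isolated
multi-localization events (removed by DBSCAN), giving the noise-rejection
stages true negatives. Per-dataset rigid offsets (tens of nm) are applied
identically to localizations and fiducial beads; beads are shared across
datasets with 0.5 nm track jitter over 10 time points.

**What passing tests do and do not show.** The generator emulates
geometry, counting statistics and localization noise; it does not emulate
optical aberrations, depletion-beam physics, imager-strand kinetics,
within-round drift, chromatic offsets, or autofluorescence structure.
Parameter-recovery results therefore validate the *computations*, not the
instruments; the published biological measurements (spot sizes, distance
medians, fold-changes) are regimes the generator targets, not values the
package claims to reproduce from real data.

## Problem sizes and seeds

Test and acceptance runs use desk-scale problems: 20 STED scenes of
128–512 px, MINFLUX scenes of ~500–700 combined events, 100 DBSCAN
fixtures of up to 300 points. All randomness flows from one seed through
named substreams (`SeedSequence([seed, crc32(name)])`), making every
pipeline run bitwise reproducible; the CLI records config hash, seed and
library versions in `provenance.json`.

## Known limitations

* The spot-FWHM fit assumes an isotropic Gaussian plus flat offset;
  elongated or overlapping spots are flagged rather than modelled.
* Alignment assumes at least one fiducial shared by all rounds and pure
  translation; rotation/scale drift is out of scope.
* The probe-design validator flags the MT-ND5 set, whose 451 covered nt
  over 5 pairs (90.2 nt/pair) exceeds the 40–60 nt footprint implied by
  two 20–30 nt regions per pair; the packaged table reproduces the design
  as published and the validator reports the inconsistency.
* Density units are per µm² of mask area; no attempt is made to infer 3D
  mitochondrial volume from 2D rasters.
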