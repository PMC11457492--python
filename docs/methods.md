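# Methods

`tuftmorph` quantifies the cytoskeletal scaffold of intestinal tuft cells —
the "tuft" of giant apical protrusions supported by crosslinked actin
bundles that descend, together with a co-aligned microtubule array, from the
apical surface toward the nucleus. The package implements four measurement
families and a synthetic-data generator that produces inputs with exact
ground truth, so every stage is validated by parameter recovery rather than
by eye.

## Filament packing (2D cross-sections)

A bundle cross-section is reduced to a set of filament-centre coordinates.
On EM-like images, centres are detected with a scale-selected
Laplacian-of-Gaussian: the LoG sigma is `expected_spacing / (2*sqrt(2))` so
the blob diameter matches half the expected centre-to-centre spacing, maxima
closer than ~0.45 spacing are suppressed, and each maximum is refined to
sub-pixel precision by an intensity-weighted centroid in a window of radius
half a spacing. Polarity (dark filaments on bright background, or inverted)
is either given or inferred from the sign of the image's mean-median skew.

Packing statistics follow from a radius-bounded neighbour graph (default
radius 12 nm centre-to-centre, about twice a filament width):

* **degree histogram** — six neighbours diagnoses hexagonal packing;
* **triplet packing angle** — at each point of degree >= 2, neighbours are
  sorted by azimuth and the angle subtended by each azimuth-consecutive
  pair is emitted (wrap-around pair only for degree >= 3, so a degree-2
  point contributes one angle). An ideal triangular lattice gives 60
  degrees; this operationalizes "the angle between a filament and two
  adjacent neighbours" without double-counting arbitrary pairs;
* **spacing** — the median of all neighbour distances within the graph
  radius. The median of each point's *nearest* neighbour distance is
  deliberately not used: under positional jitter the minimum of ~6 noisy
  distances is biased low by order-statistic selection (about -7% at jitter
  5% of spacing), while the all-neighbour median stays centred on the true
  spacing. Patterns with no within-radius neighbours fall back to the
  unbounded nearest-neighbour median so sparse inputs still get an
  estimate;
* **bundle diameter** — the minimum-enclosing-circle diameter of the
  centres plus one estimated spacing, approximating the extent of the
  outermost filaments rather than their centres. The offset is recorded in
  the summary metadata.

Medians use the midpoint convention for even counts throughout.

## Fourier lattice analysis

Periodic spacing `d` produces reflections at radius `1/d` (square) or
`2/(sqrt(3) d)` (triangular) in the power spectrum. The pipeline:

1. **Spectrum** — mean-subtracted, Hann-apodized FFT (apodization
   suppresses edge streaks in small fields); calibration `1/(N px)` nm^-1
   per bin.
2. **Reflection detection** — local maxima inside the annulus
   `[1/d_max, 1/d_min]`, accepted when their spectral *amplitude* exceeds 5x
   the median annulus amplitude, non-maximum suppressed within a 15-degree
   angular window (strongest first), completed to centrosymmetric pairs.
   Acceptance is on amplitude rather than power because periodogram power
   is approximately exponentially distributed under a spatially random
   null: over the few hundred effective annulus bins the max/median power
   ratio is routinely 10-17x, so no fixed power factor separates noise from
   signal, whereas the max/median *amplitude* ratio of the null stays near
   4 and true reflections exceed 10x. With the default factor a completely
   spatially random (CSR) pattern yields an empty reflection set.
3. **Lattice filtering** — circular mode passes an annulus at the
   magnitude-weighted mean reflection radius (half-width 15% of the
   radius); hexagonal mode passes six discs (radius 15% of the ring) at the
   detected reflections and requires exactly six usable peaks. The mask is
   applied Hermitian-symmetrically so the inverse transform is real.
4. **Back-mapping** — the filtered image is thresholded at the 0.70
   quantile of its positive values (an explicit stand-in for manual
   background thresholding); the **highlighted fraction** is the fraction
   of known centres with an on-pixel within half a spacing (configurable).

The 15% mask sizes and 0.70 quantile are explicit defaults for steps that
are interactive in standard EM practice ("as tight as possible" masks,
manual thresholds); all are exposed as parameters.

## 3D network morphometry

Binary volumes are indexed `[z, y, x]` with z the apicobasal axis (z = 0
apical); calibration is a per-axis `(x, y, z)` triple in nm.

* **Tracing** — 26-connected components are skeletonized to 1-voxel
  centrelines; the longest geodesic through each skeleton (double Dijkstra
  sweep, steps weighted by calibrated length) becomes the trace. Components
  shorter than 0.5 um are discarded as segmentation debris.
* **Pitch** — the inclination of the trace's principal axis (dominant
  covariance eigenvector) above the xy-plane: 90 degrees = vertical. The
  principal axis is preferred over the end-to-end vector for robustness to
  skeleton jitter; both are reported.
* **Interaction mapping** — the microtubule channel is dilated by N
  iterations (default 4, exposed as a parameter) of a unit-radius
  6-connected ball; an actin skeleton voxel "interacts" when it falls
  inside the dilated channel. This is equivalent to dilating actin by the
  same element and intersecting with microtubules, but measuring along the
  actin skeleton makes total actin length the natural denominator of
  `percent_interacting`. Contiguous interacting runs form segments; runs
  separated by <= 2 skeleton voxels are merged to bridge single-voxel
  dropouts, and a single-voxel run is assigned one local step length so
  every segment has positive length. A raw-voxel counterpart
  (`interaction_volume_fraction`: overlap volume / actin volume) is
  provided for masks too noisy to skeletonize meaningfully.
* **Area versus depth** — depth 0 is the first slice containing any cell
  voxel; cell area is the on-voxel count times pixel area, bundle-occupied
  area the 2D convex hull of bundle voxels in the slice (falling back to
  voxel count when degenerate). Slopes are centred ordinary least squares,
  exactly zero for constant areas.
* **Apical shape** — circularity `4 pi A / P^2` with area from the pixel
  count and perimeter from the marching-squares contour smoothed by a
  5-point circular moving average. The raw staircase contour overestimates
  the perimeter of smooth shapes by a resolution-independent ~7%, so a
  rasterized disc would plateau near 0.88; after smoothing it converges to
  1 with resolution while a square stays within ~2% of the closed-form
  pi/4.

## Linescan regionalization

Profiles are parameterized tip-to-base (apical tip at arclength 0), sampled
at unit-pixel steps by bilinear interpolation and averaged over a
perpendicular width (default 10 px). Four models cover the observed
regionalization patterns (`tuftmorph/models.py` for exact forms):

* `lognormal(amplitude, mode, shape)` — a single intracellular peak; the
  analytic peak is at `x = mode`. The value at x <= 0 is taken as the
  analytic limit 0, so no grid shift is needed to avoid `log(0)`.
* `four_pl(bottom, top, midpoint, hill)` — Boltzmann/logistic sigmoid in
  arclength. The log-x Hill parameterization is degenerate at the x = 0
  tip, so the logistic form is used; fits are canonicalized to positive
  hill so `bottom` is always the plateau on the tip side.
* `quartic(c0..c4)` — fitted in closed form (linear least squares); its
  peak is the in-span argmax via the derivative's roots.
* `exp_decay(amplitude, lambda, offset)` — signal tapering toward the
  rootlet; the documented choice for tip-to-base actin-intensity decay
  fits, selectable by flag.

Nonlinear fits use trust-region least squares with documented initial
guesses (lognormal: argmax/0.5/max; 4PL: first/last-decile plateaus,
half-range crossing, hill 1; exp_decay: log-linear seed) plus four
jittered restarts from a fixed RNG; the lowest-RSS candidate wins, and
failure returns `converged=False` with best-effort parameters instead of
raising. Aggregation resamples profiles to a common 100-point fractional
arclength grid and fits one curve through the pooled cloud (mirroring a
single fit drawn through all raw traces), rather than averaging
per-profile parameters.

## Synthetic-data generator

The generator emulates the three input types at the study's working
conditions, which are its defaults:

* **Cross-sections** — triangular (or square) lattices at 9.2-nm spacing
  clipped to a 53-nm-radius bundle disc (~120 filaments), optional
  isotropic Gaussian jitter, i.i.d. vacancies (isolated missing filaments,
  the simplest null for packing anomalies), rendered as Gaussian blobs
  (sigma 2 nm, truncated at 9 sigma so rendered values match the
  closed-form blob sum to machine precision) on a flat background with
  additive Gaussian noise, dark-on-light by default. A CSR mode (uniform
  points on the disc) is the negative control.
* **3D networks** — straight polymers with pitch ~ N(81.1, 5) degrees
  truncated to (0, 90], azimuth uniform, lengths uniform on 5-12 um, in a
  13 x 16 x 16 um volume at 100-nm voxels by default. A chosen fraction of
  microtubules copies an actin partner's direction at a fixed 200-nm
  lateral offset. Polymers of one channel are kept non-adjacent (26
  connectivity), matching the analysis assumption that segmented objects
  are individually resolvable; placement is retried up to 100 times and
  then errors, because silent truncation would bias the length truth.
* **Profiles** — any fit model evaluated on an equally spaced grid plus
  additive Gaussian noise.

What the generator deliberately does not emulate: filament curvature (pitch
and interaction metrics depend only on direction and length), correlated
dislocation lines, membrane wrapping and vesicles, and realistic EM texture
or shot noise (noise is additive Gaussian; the real images' noise
statistics are unknown, so `noise_sd` is a free parameter flagged in
configs). Passing recovery tests therefore demonstrates correctness of the
measurement code under known geometry — not robustness to every artefact of
real micrographs.

## Reproducibility

Every generator takes an explicit seed; identical specs give bit-identical
outputs. In pipeline runs all randomness derives from one global seed via
`SeedSequence([global_seed, stage_index])`, so any stage can be re-run in
isolation. Reports contain no timestamps and list outputs relative to the
run directory, making repeat runs byte-comparable.

Problem sizes used by the test suite and the acceptance script — 256-px
cross-sections with ~120 filaments, networks of 50-200 polymers in
130 x 200 x 200-voxel volumes, 30-50 noisy profiles per recovery check —
are chosen so each stage's statistics are well-resolved while a full run
completes in seconds.

## Known limitations

* Interaction lengths on fully co-aligned synthetic pairs span the whole
  polymer, so their medians are generator statements, not predictions of
  contact-length distributions in tissue (real polymers are curved and
  contact intermittently).
* The highlighted-fraction metric is permissive at the default 0.70
  threshold: weakly ordered patterns inside the bundle footprint can still
  score moderately high; it is a *relative* order measure, strongest in
  jitter-sweep comparisons.
* Skeleton-based lengths overestimate continuous lengths by a few percent
  (staircase effect at 26-connectivity); percentages of length are largely
  insensitive because numerator and denominator share the bias.
* `detect_centers` assumes roughly uniform blob size; bundles with mixed
  filament diameters would need a multi-scale detector.
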