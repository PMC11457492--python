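# tuftmorph

Morphometry of the tuft-cell cytoskeleton: quantitative image analysis for
the giant apical protrusion array ("tuft") of intestinal tuft cells, whose
core actin bundles — each a crosslinked array of ~100 hexagonally packed
filaments — descend from the apical membrane to the perinuclear region
alongside a co-aligned microtubule network.

The package is for microscopists and image analysts who have cross-section
EM images, segmented 3D two-channel volumes, or intensity linescans of such
cells (or want ground-truthed synthetic versions of them) and need
reproducible numbers instead of interactive measurements. It provides:

* **packing** — filament/bundle centre detection (sub-pixel
  Laplacian-of-Gaussian) and point-pattern statistics: neighbour counts
  within a 12-nm radius, the triplet packing angle (60° on an ideal
  hexagonal lattice), centre-to-centre spacing, bundle diameter;
* **lattice_fourier** — power-spectrum reflection detection, circular or
  hexagonal Fourier masking, inverse filtering and thresholded back-mapping
  of lattice-ordered filaments, with the fraction of centres highlighted;
* **network3d** — skeleton tracing of polymers in binary volumes, pitch
  relative to the apicobasal axis (90° = vertical), actin–microtubule
  interaction segments via iterated dilation overlap, bundle/cell area as a
  function of depth, apical area and circularity;
* **linescan** — tip-to-base intensity profiles averaged over a
  perpendicular width, fitted with lognormal, sigmoidal 4PL, fourth-order
  polynomial or exponential-decay models, singly or pooled;
* **synthetic_data** — seeded generators for all of the above with exact
  ground truth (jittered hexagonal lattices with vacancies rendered as
  EM-like images; straight-polymer 3D networks with controlled pitch,
  length and pairing; noisy model profiles).

The core diagnostic quantities, in the field's notation: for filament
centres with neighbour set N(i) within radius r = 12 nm, the packing angle
at focal point i is the angle subtended by azimuth-consecutive pairs of
N(i); a triangular lattice of spacing d gives first-order Fourier
reflections at radius 2/(√3·d); polymer pitch is
θ = arcsin(|v_z|/‖v‖) for the trace's principal axis v; interaction
percent is 100 · (interacting actin skeleton length) / (total actin
length), with "interacting" meaning within N dilation steps of the
microtubule channel.

## Worked example

Generate a jittered hexagonal bundle cross-section (9.2-nm spacing, 53-nm
bundle radius), detect the filaments, and measure packing and lattice
order:

```python
import tuftmorph as tm

spec = tm.LatticeSpec("hex", spacing_nm=9.2, jitter_sd_nm=0.46,
                      bundle_radius_nm=53.0, center_nm=(128.0, 128.0), seed=0)
points, truth = tm.gen_lattice_points(spec)
image = tm.render_cross_section(points, tm.RenderSpec(
    pixel_size_nm=1.0, psf_sigma_nm=2.0, noise_sd=0.02,
    image_shape_px=(256, 256), seed=1))

detected = tm.detect_centers(image, expected_spacing_nm=9.2)
graph = tm.build_neighbor_graph(detected, radius_nm=12.0)
summary = tm.summarize_packing(detected, graph)
print(f"filaments detected:   {summary.n_points}")
print(f"median spacing:       {summary.estimated_spacing_nm:.2f} nm")
print(f"median packing angle: {summary.median_triplet_angle_deg:.1f} deg")
print(f"bundle diameter:      {summary.bundle_diameter_nm:.1f} nm")

refl = tm.detect_reflections(tm.power_spectrum(image), (7.0, 12.0))
result = tm.lattice_filter(image, refl, "hexagonal")
frac = tm.highlighted_fraction(result, detected)
print(f"reflections:          {len(refl)} at {refl.ring_radius_nm_inv:.4f} /nm")
print(f"highlighted fraction: {100*frac:.1f} %")
```

Output:

```
filaments detected:   120
median spacing:       9.21 nm
median packing angle: 62.2 deg
bundle diameter:      113.0 nm
reflections:          6 at 0.1256 /nm
highlighted fraction: 100.0 %
```

All 120 generated filaments are found; the measured spacing matches the
9.2-nm construction value; the six reflections sit at the reciprocal
triangular-lattice radius 2/(√3·9.2) ≈ 0.1255 nm⁻¹; and the hexagonal
Fourier filter highlights every filament — a strongly ordered bundle. The
packing-angle median drifts a couple of degrees above 60° because jitter
broadens the angle distribution asymmetrically (angles are bounded below by
neighbour exclusion).

The same analyses run from the shell on TIFF/CSV inputs:

```bash
tuftmorph simulate --config config.yaml --outdir out/
tuftmorph packing  --image out/cross_section.tif --expected-spacing-nm 9.2 --outdir out/
tuftmorph fft      --image out/cross_section.tif --mode hexagonal --outdir out/
tuftmorph network  --actin actin.tif --mt mt.tif --outdir out/
tuftmorph linescan --profiles-csv profiles.csv --model lognormal --outdir out/
tuftmorph run      --config config.yaml   # full simulate -> analyze pipeline
```

A single YAML config drives a full run; every artifact (points, edges,
traces, interaction segments, fits) is written as CSV/JSON next to a
`report.json` whose contents are byte-identical across repeat runs with the
same seed.

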