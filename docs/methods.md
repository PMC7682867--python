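# Methods

This note documents the models, numerical choices and limitations behind
`tubemorph`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The embryo phantom

The phantom stands in for a transverse block of embryonic neural tube.
Its geometry is deliberately minimal while still supporting every
measurement the pipeline makes:

- the **tube** is a solid half-cylinder (default radius 40 µm) whose flat
  face is the medial surface at x = 0, with the cylinder axis along the
  antero-posterior y axis;
- the **apical cavity (lumen)** is a thin slit (default 3 µm) along the
  medial face, extended dorso-ventrally — the target of all
  distance-to-apical measurements;
- everything outside the tube plays the role of adjacent mesenchyme, the
  destination of emigrated nuclei.

Axes follow the embryo convention: x medial-lateral, y antero-posterior,
z dorso-ventral. Arrays are indexed (z, y, x), images (c, z, y, x).
Voxels are 0.5 µm isotropic by default (a nucleus of semi-axes
(2, 2, 3) µm then spans ≈ 400 voxels, comfortably above the 95-voxel
quality floor) with physical positions at voxel centres.

**Nuclei** are uniform solid ellipsoids. The two tissue states encode the
phenotypes being contrasted:

| parameter | epithelial preset | mesenchymal preset |
|---|---|---|
| semi-axes (µm) | (2, 2, 3) → true prolate ellipticity 0.4 | (2, 2.2, 2.6) → 0.167 |
| orientation | medial-lateral ± 5° jitter | uniform on the sphere |
| emigration probability | 0 | 0.2 per nucleus |
| clusters | none | 8 chains of 5 cells, spacing ≤ 9 µm |
| n | 200 | 500 |

The control semi-axes are chosen so that the elongated-epithelium
ellipticity calibration sits at 2(3−2)/(3+2) = 0.4, and the orientation
convention centres at θ = 90°, φ = 0°. The transformed-state axes are a
design choice (no printed value exists for it); 0.167 makes the state
clearly rounder without being spherical. Orientation jitter rotates the
medial-lateral target axis about a uniformly random axis by an angle
drawn as |Normal(0, 5°)|. Emigration flags come from a single documented
draw of the `emigration` substream, so tests can replay the exact
binomial realisation. Cluster members are placed as chains — each new
member within (contact distance, spread] of a previous member — which
guarantees single-linkage connectivity at the DBSCAN radius while
keeping nuclei physically disjoint.

Rendering order matters and is fixed: ground truth is frozen first, then
ellipsoids are painted (DNA ≈ 200, GFP/marker 150 of a 255 dynamic
range), blurred with a small Gaussian (σ = 0.4 µm), saturated debris
blobs (< 95 voxels, painted at twice the dynamic maximum so they clip to
saturation) are added, per-slice exponential attenuation and additive
Gaussian noise (σ = 2–4) are applied, and the image is clipped to
[0, 255].

**What the phantom does not emulate**: chromatin texture (nuclei are
uniform), anisotropic PSFs, optical sectioning artefacts, touching or
overlapping nuclei (placement enforces a minimum separation, 7 µm by
default), tissue deformation, and autofluorescence structure beyond a
constant offset. Passing tests therefore demonstrate that the
measurement chain is correct for resolvable, well-stained nuclei; they
do not certify performance on densely packed or poorly resolved real
tissue.

**DNA-content events** are simulated per the flat-S model: G0/G1 content
at the G1 mean, G2/M at twice that, S uniform in between, all measured
with relative Gaussian noise of coefficient of variation `cv` (3% default,
a realistic flow-cytometry peak width).

## Segmentation and preprocessing

- **Thresholding.** A single global Otsu pass on a sparse-foreground
  stack lands near the background mode and dilates every object with its
  blur skirt — an additive bias that distorts axis ratios (measured
  prolate ellipticity dropped to ≈ 0.31 under it). The implementation
  therefore runs Otsu twice: the first pass separates background, the
  second (on super-threshold, non-saturated voxels) cuts within the
  blurred edge. The resulting erosion is multiplicative, which
  ratio-based shape metrics are invariant to, and on unblurred images the
  second pass is degenerate and the exact first-pass mask is kept.
  Saturated voxels are excluded from both statistics so debris cannot
  drag the threshold.
- **Splitting.** Touching nuclei are split by a watershed on the negated
  Euclidean distance transform (computed with physical sampling, so
  anisotropic voxels are honoured), seeded at smoothed-EDT maxima no
  closer than `min_seed_distance_um` (default 4 µm, just below the
  smallest nuclear diameter).
- **Quality filter.** Objects with fewer than 95 voxels are removed
  (95-voxel objects are kept — the strict inequality), as are objects
  with more than 50% saturated voxels in the DNA channel. The filter is
  idempotent and survivors are relabelled consecutively.
- **Bleach/depth correction.** Depth attenuation is multiplicative and
  smooth in z, so the per-slice gain comes from a log-linear fit of slice
  means against slice index rather than from raw slice-mean division:
  raw means are dominated by how many nuclei happen to intersect a slice,
  and dividing by them injects that content noise into every voxel
  (in testing it destroyed segmentation on sparse stacks). The fitted
  exponential recovers a true exponential decay exactly.
- **Background subtraction** (GFP channel) is a grey-scale top-hat with a
  separable box structuring element (half-width 6 µm by default). A ball
  element costs O(N·r³) and is impractical on multi-megavoxel stacks;
  the box is separable, removes any flat offset exactly and preserves
  features smaller than the element.
- **Positivity.** Marker counting is automated as a mean-intensity
  threshold per object (default 50, between background and the 150
  rendered signal); per-object statistics are computed on raw channels so
  the saturation level keeps its meaning.

## Morphometry

Semi-axes come from the second-moment relation for uniform solid
ellipsoids, λ = a²/5, with Sheppard's correction (+h²/12 per axis) for
voxel-centre sampling. Points must be non-coplanar; degeneracy is
detected on the raw covariance before correction. With exactly equal
ground-truth minor axes (a = b) the eigendecomposition splits the
degenerate pair by sampling noise, ordering inflates b̂ slightly, and the
measured mean prolate ellipticity lands near 0.375 instead of 0.400 at
n ≈ 400 voxels per nucleus — within the ±0.05 calibration band; the bias
shrinks as voxel counts grow.

Orientation angles fold the axis into the x ≥ 0 half-space (ties broken
toward y ≥ 0, then z ≥ 0), making θ ∈ [0°, 180°] and φ ∈ (−90°, 90°]
invariant under sign flips of the axis.

## Spatial statistics

Distance to the apical surface is the Euclidean distance transform of
the cavity complement, sampled at each centre's containing voxel — zero
inside the cavity, and exact (it matches exhaustive nearest-cavity-voxel
search to machine precision on random instances). Emigration is a
separate binary call against the tube mask, restricted to GFP+ nuclei.

DBSCAN uses eps = 10 µm and minPts = 3 with the point counting itself;
a post-hoc floor demotes any cluster below 3 members (a no-op for plain
DBSCAN but stated behaviour). The cluster-size distribution is fitted as
A·e^(−k·size) by least squares on log percentages over realised size
classes. The unweighted log fit carries Jensen bias from sparse tail
classes (≈ −0.12 at 200 geometric samples, Monte-Carlo sd ≈ 0.08); a
weighted variant was deliberately not added to keep the estimator simple
and reproducible.

## Dean–Jett–Fox fitting

The histogram model is w₁·N(µ₁, σ₁) + w₂·N(µ₂, σ₂) + wₛ·S with
S(x) = [Φ((x−µ₁)/σ₁) − Φ((x−µ₂)/σ₂)]/(µ₂−µ₁) — a flat S compartment
convolved with a Gaussian whose width interpolates between the two peak
widths. The classical formulation broadens a low-order polynomial S; the
flat variant is the standard simplification and matches the simulator,
so recovery is limited only by sampling noise (phase fractions within
±0.011 at n = 20 000, cv = 3%; |bias| < 0.002 over 25 seeds; S-fraction
RMSE grows 0.005 → 0.017 as cv goes 3% → 10%).

Fitting is bounded trust-region least squares on bin counts (256 bins),
unweighted for determinism. Initialisation is deterministic: µ₁ at the
highest-count bin inside the G1 constraint range, µ₂ = 2µ₁ clipped into
the G2 range, σ = 5% of the mean, component masses from the histogram
split at the peak midpoint. Peak widths are bounded below by one bin
width so the fit cannot collapse. The G1 range must overlap the
histogram support; an empty G2 range is legal (a pure-G1 sample drives
the G2 amplitude to zero). Below 500 events the fit proceeds with a
warning.

## Statistics

Mann–Whitney U uses midranks; the p-value is exact (full null
enumeration) when the smaller group has ≤ 8 values and the pooled sample
is tie-free, otherwise the tie-corrected normal approximation with
continuity correction. Two-sided throughout. For count-based metrics the
unit of replication is the embryo (per-embryo positive percentages,
mean ± s.e.m. across embryos, embryos without GFP+ cells excluded with a
warning); intensity metrics stay at the per-cell level.

## Determinism and problem sizes

All randomness flows from one root seed through named CRC-keyed
substreams (`placement`, `orientation`, `markers`, `noise`, `debris`,
`emigration`, one per condition/stage), so identical configurations
reproduce truth tables, images, CSVs and reports bit-for-bit; report
floats are written at 9 significant digits. The shipped problem sizes —
200-nucleus control and 500-nucleus transformed phantoms, 20 000-event
DNA histograms — keep every analysis comfortably inside a desk-scale
run (the full acceptance script completes in well under a minute on one
CPU) while leaving binomial/sampling noise far smaller than the
calibration tolerances.

## Known limitations

- The segmentation is tuned for resolvable nuclei; heavily overlapping
  nuclei merge (the generator's minimum-separation constraint reflects
  this, and detection below ~3.5 µm centre separation is not claimed).
- The prolate-ellipticity convention 2(c−b)/(b+c) is one of several in
  commercial software; it is exposed as the documented formula rather
  than matched to any particular vendor.
- The flat-S Dean–Jett–Fox variant is exact for the simulator but an
  approximation for real S-phase kinetics; a polynomial S compartment
  would be the extension point.
- FCS files are not parsed; DNA-content events arrive as CSV tables
  (pre-gated, with a GFP flag).
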