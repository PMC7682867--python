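# tubemorph

Quantitative 3D tissue morphometry and cell-cycle analysis for the
embryonic neural tube, built around a synthetic embryo-phantom generator.

## The problem

When an oncogenic transcription factor such as PAX3-FOXO1 transforms
neuroepithelial cells, the tissue phenotype changes along several
measurable axes: nuclei become rounder, their major axes lose alignment
with the medial-lateral tissue axis, cells detach from the apical surface
and emigrate beyond the neural tube, emigrated cells aggregate into
clusters, and the cell-cycle phase distribution shifts. `tubemorph`
implements the measurement chain for all of these readouts:

- **Morphometry** — nuclei segmented from a DNA-stain channel (two-stage
  Otsu threshold + watershed on the Euclidean distance transform) are
  summarised by moment-matched ellipsoids: for a uniform solid ellipsoid
  the covariance eigenvalues are (a²/5, b²/5, c²/5), so semi-axes follow
  as √(5λ). Shape is reported as prolate ellipticity 2(c−b)/(b+c)
  (0 for a sphere), oblate ellipticity 2(b−a)/(a+b), and sphericity
  π^⅓(6V)^⅔/A (Knud Thomsen surface-area approximation).
- **Orientation** — the major axis in embryo polar coordinates: θ, the
  deviation from the dorso-ventral z axis, and φ, the azimuth within the
  medial-lateral/antero-posterior plane. An epithelium aligned to the
  medial-lateral axis centres on θ = 90°, φ = 0°.
- **Migration** — per-nucleus distance to the apical (luminal) surface via
  a physically sampled distance transform, and the fraction of GFP+
  nuclei whose centres lie outside the neural-tube mask (emigration).
- **Cohesion** — DBSCAN clustering of nucleus centres (10 µm
  neighbourhood, minimum 3 cells per cluster) and an exponential decay
  fit A·e^(−k·size) of the percentage of clusters per size class.
- **Cell cycle** — Dean–Jett–Fox deconvolution of univariate DNA-content
  histograms: Gaussian G0/G1 and G2/M peaks plus a flat S compartment
  convolved with an interpolating Gaussian, fitted by bounded least
  squares under user-constrained G1/G2 mean ranges.
- **Statistics** — per-embryo positive-fraction summaries and two-sided
  Mann–Whitney U comparisons (exact for small tie-free samples).

No microscope data are required: the `phantom` module renders
multi-channel voxel stacks of a half-cylindrical neural tube with a slit
lumen, nuclei as solid ellipsoids with configurable shape, orientation
jitter, emigration probability, seeded clusters, marker positivity, image
noise, depth attenuation and saturated debris — together with the
ground-truth table every measurement can be audited against.

## Worked example

```sh
tubemorph run-all --config configs/example.yaml --out demo
tubemorph report --run-dir demo
```

prints (seed 42):

```
condition control:
  n_nuclei: 60
  mean_prolate_ellipticity: 0.3706
  median_theta_deg: 90.08
  median_phi_deg: -0.2819
  emigration_pct: 0
condition fusion:
  n_nuclei: 80
  mean_prolate_ellipticity: 0.1622
  median_theta_deg: 95.63
  median_phi_deg: 15.02
  emigration_pct: 13.75
control vs fusion (prolate_ellipticity): U=4800.0, p=5.32e-24
```

The control condition reads like an epithelium: elongated nuclei
(prolate ellipticity ≈ 0.4 for 2:2:3 axes), major axes centred on the
medial-lateral direction (θ ≈ 90°, φ ≈ 0°), nothing outside the tube.
The transformed condition is rounder (0.16), disordered in orientation,
and 13.75% of its nuclei have left the tube; the rank-sum test confirms
the shape difference. Per-condition outputs (rendered TIFF stacks, masks,
ground-truth and measured nucleus tables, cluster tables, a JSON report)
land in the output directory; `demo/fusion/nuclei.csv` holds the
per-nucleus measurements.

The same analyses are available as a library:

```python
import tubemorph as tm
from tubemorph.pipeline import analyze_phantom

phantom = tm.generate_phantom(tm.phantom.epithelial_preset(seed=11))
nuclei, summary, clusters = analyze_phantom(phantom)
print(summary["mean_prolate_ellipticity"])   # ~0.38 for (2, 2, 3) µm nuclei
```

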