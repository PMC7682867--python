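# Two-condition demonstration run: an epithelial control and a
# PAX-FOXO1-like transformed condition. Sizes are kept small so the run
# finishes in well under a minute; the presets in tubemorph.phantom carry
# the full study conditions.
seed: 42
out_dir: tubemorph_run
conditions:
  control:
    state: epithelial
    n_nuclei: 60
    semi_axes_um: [2.0, 2.0, 3.0]
    orientation_noise_deg: 5.0
    volume_um: [70.0, 90.0, 45.0]
    noise_sd: 2.0
    n_debris: 5
    marker_probs: {edu: 0.95}
  fusion:
    state: mesenchymal
    n_nuclei: 80
    semi_axes_um: [2.0, 2.2, 2.6]
    emigration_prob: 0.2
    cluster_spec: {n_clusters: 4, cluster_size: 5, spread_um: 9.0}
    volume_um: [90.0, 90.0, 45.0]
    noise_sd: 2.0
    n_debris: 5
    marker_probs: {edu: 0.5}
analysis:
  filter_params: {min_voxels: 95, max_saturated_fraction: 0.5}
  cluster_params: {eps_um: 10.0, min_cluster_size: 3}
  positivity_thresholds: {gfp: 50.0, edu: 50.0}
djf:
  control: {n_events: 20000, fractions: [0.35, 0.50, 0.15], cv: 0.03}
  fusion: {n_events: 20000, fractions: [0.60, 0.25, 0.15], cv: 0.03}
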