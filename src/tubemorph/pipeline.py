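"""End-to-end orchestration: phantom -> preprocess -> segment -> morphometry
-> spatial statistics -> group comparisons -> report bundle.

`analyze_phantom` runs the measurement chain on one rendered volume and
returns a per-nucleus table plus headline summary metrics; `run_pipeline`
drives it over every configured condition, writes all artefacts (TIFF
stacks, CSV tables, JSON report) and performs cross-condition rank-sum
comparisons. All randomness flows from one root seed through named
substreams, so a fixed config reproduces the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from tubemorph._rng import child_seed
from tubemorph.cellcycle import DjfConstraints, fit_dean_jett_fox, histogram_events
from tubemorph.imageproc import (
    QualityFilterParams,
    bleach_correct,
    classify_positive,
    quality_filter,
    segment_nuclei,
    subtract_background,
)
from tubemorph.morphometry import fit_ellipsoid, orientation_angles, shape_metrics
from tubemorph.phantom import (
    ClusterSpec,
    EmbryoFrame,
    PhantomConfig,
    TissuePhantom,
    generate_phantom,
    simulate_dna_events,
)
from tubemorph.spatial import ClusterParams, dbscan_clusters, distance_to_apical, emigration_fraction
from tubemorph.stats import mann_whitney_u

__all__ = ["RunConfig", "AnalysisParams", "run_pipeline", "analyze_phantom", "load_config"]

log = logging.getLogger("tubemorph")

_CSV_FLOAT = "%.9g"


@dataclass(frozen=True)
class AnalysisParams:
    """Measurement-chain knobs shared by every condition."""

    filter_params: QualityFilterParams = QualityFilterParams()
    cluster_params: ClusterParams = ClusterParams()
    positivity_thresholds: dict[str, float] = field(default_factory=lambda: {"gfp": 50.0})
    background_radius_um: float = 6.0
    min_seed_distance_um: float = 4.0


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: phantom config per condition + analysis parameters."""

    conditions: dict[str, PhantomConfig]
    analysis: AnalysisParams = AnalysisParams()
    djf: dict | None = None  # optional synthetic cell-cycle block per condition
    out_dir: str = "tubemorph_run"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("config must define at least one condition")


_BLOCK_TYPES = {
    "filter_params": QualityFilterParams,
    "cluster_params": ClusterParams,
}


def _build(cls, mapping: dict, context: str):
    if not isinstance(mapping, dict):
        raise ValueError(f"config field {context!r} must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown field(s) {sorted(unknown)} in config section {context!r}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {context!r}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    if "conditions" not in raw or not raw["conditions"]:
        raise ValueError("config field 'conditions' is required and must be non-empty")
    conditions = {}
    for label, cond in raw["conditions"].items():
        cond = dict(cond)
        if isinstance(cond.get("cluster_spec"), dict):
            cond["cluster_spec"] = _build(ClusterSpec, cond["cluster_spec"], f"conditions.{label}.cluster_spec")
        if "semi_axes_um" in cond:
            cond["semi_axes_um"] = tuple(cond["semi_axes_um"])
        if "volume_um" in cond:
            cond["volume_um"] = tuple(cond["volume_um"])
        conditions[label] = _build(PhantomConfig, cond, f"conditions.{label}")
    analysis_raw = dict(raw.get("analysis", {}))
    for key, cls in _BLOCK_TYPES.items():
        if key in analysis_raw:
            analysis_raw[key] = _build(cls, analysis_raw[key], f"analysis.{key}")
    analysis = _build(AnalysisParams, analysis_raw, "analysis")
    return RunConfig(
        conditions=conditions,
        analysis=analysis,
        djf=raw.get("djf"),
        out_dir=raw.get("out_dir", "tubemorph_run"),
        seed=int(raw.get("seed", 0)),
        verbosity=raw.get("verbosity", "INFO"),
    )


def analyze_phantom(phantom: TissuePhantom, params: AnalysisParams = AnalysisParams()):
    """Run the measurement chain on one phantom.

    Steps: bleach-correct the DNA channel; top-hat background subtraction
    on the GFP channel; Otsu + watershed segmentation with per-channel
    statistics; size/saturation quality filter; per-nucleus ellipsoid fit,
    shape metrics, orientation angles, compartment call and apical
    distance; intensity-threshold positivity per marker channel; GFP+
    emigration fraction and DBSCAN clustering.

    Returns (nuclei DataFrame, summary dict, cluster DataFrame).
    """
    frame = phantom.frame
    chans = phantom.channels
    dna = bleach_correct(chans["dna"])
    # stats channels stay on the raw intensity scale (so the saturation
    # level keeps its meaning); only GFP gets autofluorescence removal
    processed = {"dna": chans["dna"].astype(np.float64)}
    if "gfp" in chans:
        processed["gfp"] = subtract_background(chans["gfp"], params.background_radius_um, frame)
    for name, vol in chans.items():
        processed.setdefault(name, vol.astype(np.float64))

    seg = segment_nuclei(
        dna,
        frame,
        min_seed_distance_um=params.min_seed_distance_um,
        channels=processed,
        saturation_level=phantom.config.dynamic_max,
    )
    n_raw = seg.n_objects
    seg = quality_filter(seg, params.filter_params)
    log.info("segmented %d objects, %d after quality filter", n_raw, seg.n_objects)

    marker_names = [c for c in phantom.channel_names if c not in ("dna",)]
    flags = {}
    for name in marker_names:
        thr = params.positivity_thresholds.get(name, params.positivity_thresholds.get("gfp", 50.0))
        flags[name] = classify_positive(seg, name, thr)

    rows = []
    for i, obj in enumerate(seg.objects):
        pts = frame.to_physical(obj.coords.astype(float))
        fit = fit_ellipsoid(pts, frame)
        sm = shape_metrics(fit, obj.voxel_count, frame)
        ang = orientation_angles(fit.major_axis, frame)
        vox = frame.to_voxel(fit.centre_um)
        in_tube = bool(phantom.tube_mask[tuple(vox)]) if _inside(vox, phantom.tube_mask.shape) else False
        row = {
            "label": obj.label,
            "x_um": fit.centre_um[0],
            "y_um": fit.centre_um[1],
            "z_um": fit.centre_um[2],
            "voxel_count": obj.voxel_count,
            "semi_a_um": fit.semi_axes_um[0],
            "semi_b_um": fit.semi_axes_um[1],
            "semi_c_um": fit.semi_axes_um[2],
            "major_x": fit.major_axis[0],
            "major_y": fit.major_axis[1],
            "major_z": fit.major_axis[2],
            "prolate_ellipticity": sm.prolate_ellipticity,
            "oblate_ellipticity": sm.oblate_ellipticity,
            "sphericity": sm.sphericity,
            "theta_deg": ang.theta_deg,
            "phi_deg": ang.phi_deg,
            "compartment": "in_tube" if in_tube else "emigrated",
        }
        for name in marker_names:
            row[f"{name}_positive"] = int(flags[name][i])
        rows.append(row)
    nuclei = pd.DataFrame(rows)

    summary: dict = {"n_objects_raw": n_raw, "n_nuclei": int(len(nuclei))}
    clusters = pd.DataFrame()
    if len(nuclei):
        centres = nuclei[["x_um", "y_um", "z_um"]].to_numpy()
        nuclei["apical_distance_um"] = distance_to_apical(centres, phantom.cavity_mask, frame)
        gfp = nuclei["gfp_positive"].to_numpy(dtype=bool) if "gfp_positive" in nuclei else np.ones(len(nuclei), bool)
        summary.update(
            mean_prolate_ellipticity=float(nuclei["prolate_ellipticity"].mean()),
            median_prolate_ellipticity=float(nuclei["prolate_ellipticity"].median()),
            mean_sphericity=float(nuclei["sphericity"].mean()),
            median_theta_deg=float(nuclei["theta_deg"].median()),
            median_phi_deg=float(nuclei["phi_deg"].median()),
            mean_apical_distance_um=float(nuclei["apical_distance_um"].mean()),
            n_gfp_positive=int(gfp.sum()),
        )
        if gfp.any():
            summary["emigration_pct"] = 100.0 * emigration_fraction(
                centres, gfp, phantom.tube_mask, frame
            )
            cres = dbscan_clusters(centres[gfp], params.cluster_params)
            nuclei["cluster_id"] = -1
            nuclei.loc[gfp, "cluster_id"] = cres.labels
            summary["n_clusters"] = int(cres.sizes.size)
            summary["pct_cells_in_clusters"] = (
                100.0 * float(np.mean(cres.labels >= 0)) if cres.labels.size else 0.0
            )
            if cres.exp_fit is not None:
                summary["cluster_size_exp_A"] = cres.exp_fit[0]
                summary["cluster_size_exp_k"] = cres.exp_fit[1]
            clusters = pd.DataFrame({"cluster_id": np.arange(cres.sizes.size), "size": cres.sizes})
        for name in marker_names:
            if name == "gfp":
                continue
            denom = gfp.sum()
            if denom:
                pos = float(np.mean(flags[name][gfp])) * 100.0
                summary[f"{name}_positive_pct_of_gfp"] = pos
    return nuclei, summary, clusters


def _inside(vox: np.ndarray, shape) -> bool:
    return bool(np.all(vox >= 0) and np.all(vox < np.asarray(shape)))


def _write_phantom(phantom: TissuePhantom, out: Path) -> None:
    tifffile.imwrite(out / "image.tif", phantom.image.astype(np.float32))
    tifffile.imwrite(out / "tube_mask.tif", phantom.tube_mask.astype(np.uint8))
    tifffile.imwrite(out / "cavity_mask.tif", phantom.cavity_mask.astype(np.uint8))
    phantom.truth.to_csv(out / "truth.csv", index=False, float_format=_CSV_FLOAT)
    meta = {
        "axis_order": "CZYX",
        "channel_names": phantom.channel_names,
        "voxel_size_um_xyz": list(phantom.frame.voxel_size),
        "origin_um_xyz": list(phantom.frame.origin),
    }
    (out / "frame.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _fit_condition_cellcycle(label: str, block: dict, seed: int) -> dict:
    n = int(block.get("n_events", 20000))
    fractions = tuple(block.get("fractions", (0.6, 0.3, 0.1)))
    g1_mean = float(block.get("g1_mean", 100.0))
    cv = float(block.get("cv", 0.03))
    events = simulate_dna_events(n, fractions, g1_mean=g1_mean, cv=cv, seed=child_seed(seed, f"dna/{label}"))
    hist = histogram_events(events["dna_content"].to_numpy(), n_bins=256)
    constraints = DjfConstraints(
        g1_range=tuple(block.get("g1_range", (0.8 * g1_mean, 1.2 * g1_mean))),
        g2_range=tuple(block.get("g2_range", (1.6 * g1_mean, 2.4 * g1_mean))),
    )
    fit = fit_dean_jett_fox(hist, constraints)
    g1, s, g2m = fit.phase_fractions
    return {"pct_g1": 100.0 * g1, "pct_s": 100.0 * s, "pct_g2m": 100.0 * g2m, "rss": fit.rss}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every condition and write the report bundle.

    Per condition: the rendered stack and masks (TIFF), ground-truth and
    measured nucleus tables (CSV), cluster table (CSV) and a summary block
    in ``report.json``. Across conditions: pairwise Mann-Whitney U
    comparisons of prolate ellipticity (``comparisons.csv``). A condition
    that fails is logged and skipped; the others proceed.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "conditions": {}, "errors": {}}
    values_for_stats: dict[str, np.ndarray] = {}

    for label, base_cfg in config.conditions.items():
        out = out_root / label
        out.mkdir(parents=True, exist_ok=True)
        try:
            cfg = dataclasses.replace(base_cfg, seed=child_seed(config.seed, f"phantom/{label}"))
            log.info("condition %s: generating phantom (state=%s, n=%d, seed=%d)", label, cfg.state, cfg.n_nuclei, cfg.seed)
            phantom = generate_phantom(cfg)
            _write_phantom(phantom, out)
            nuclei, summary, clusters = analyze_phantom(phantom, config.analysis)
            nuclei.to_csv(out / "nuclei.csv", index=False, float_format=_CSV_FLOAT)
            clusters.to_csv(out / "clusters.csv", index=False, float_format=_CSV_FLOAT)
            summary["config"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(cfg).items()
                if not isinstance(v, dict)
            }
            if config.djf and label in config.djf:
                summary["cell_cycle"] = _fit_condition_cellcycle(label, config.djf[label], config.seed)
            report["conditions"][label] = summary
            if len(nuclei):
                values_for_stats[label] = nuclei["prolate_ellipticity"].to_numpy()
        except Exception as exc:  # isolate per-condition failures
            log.error("condition %s failed: %s", label, exc)
            report["errors"][label] = str(exc)

    comparisons = []
    labels = list(values_for_stats)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            u, p = mann_whitney_u(values_for_stats[labels[i]], values_for_stats[labels[j]])
            comparisons.append(
                {"group_a": labels[i], "group_b": labels[j], "metric": "prolate_ellipticity", "U": u, "p": p}
            )
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out_root / "comparisons.csv", index=False, float_format=_CSV_FLOAT)
        report["comparisons"] = comparisons

    (out_root / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
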