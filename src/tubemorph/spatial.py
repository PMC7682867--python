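"""Migration and cohesion statistics: distance to the apical surface,
emigration out of the tube, DBSCAN clustering and cluster-size decay.

Distances to the apical (luminal) surface are read off a Euclidean
distance transform of the cavity-mask complement, computed with physical
voxel sampling, so a nucleus centre inside the cavity scores 0. Emigration
is a separate binary call: a GFP+ centre whose voxel falls outside the
neural-tube mask has left the epithelium.

Cell clustering follows DBSCAN with a 10 um neighbourhood and a minimum
of 3 cells per cluster (the point itself counts); clusters below the
minimum size are never emitted. The percentage of clusters per size class
is summarised by an exponential decay A exp(-k size), fitted by least
squares on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from tubemorph.phantom import EmbryoFrame

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "DistanceResult",
    "distance_to_apical",
    "emigration_fraction",
    "dbscan_clusters",
    "fit_cluster_size_distribution",
    "nearest_neighbour_distances",
]


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: neighbourhood radius (um) and minimum cluster size."""

    eps_um: float = 10.0
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if self.eps_um <= 0:
            raise ValueError("eps_um must be > 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class DistanceResult:
    """Per-nucleus distance (um) to the nearest cavity voxel plus the
    in_tube / emigrated compartment call."""

    distances_um: np.ndarray
    compartment: np.ndarray  # "in_tube" | "emigrated"


@dataclass
class ClusterResult:
    """DBSCAN labels (-1 = noise), per-cluster sizes, the % of clusters per
    realised size class, and the exponential fit (A, k, rss) of that
    distribution (None when fewer than two size classes exist)."""

    labels: np.ndarray
    sizes: np.ndarray
    size_classes: np.ndarray
    percentages: np.ndarray
    exp_fit: tuple[float, float, float] | None


def _centres_to_voxels(centres_um: np.ndarray, mask_shape: tuple[int, ...], frame: EmbryoFrame) -> np.ndarray:
    idx = frame.to_voxel(np.asarray(centres_um, dtype=float))
    for i, p in enumerate(idx):
        if np.any(p < 0) or np.any(p >= np.asarray(mask_shape)):
            raise ValueError(f"centre {np.asarray(centres_um)[i]} um falls outside the volume")
    return idx


def distance_to_apical(centres_um: np.ndarray, cavity_mask: np.ndarray, frame: EmbryoFrame) -> np.ndarray:
    """Distance (um) from each nucleus centre to the nearest cavity voxel.

    The distance transform of the cavity complement is computed with the
    frame's physical sampling and sampled at each centre's containing voxel.
    Raises for an empty cavity mask or a centre outside the volume.
    """
    cavity = np.asarray(cavity_mask, dtype=bool)
    if not cavity.any():
        raise ValueError("cavity mask is empty; apical distance undefined")
    centres = np.atleast_2d(np.asarray(centres_um, dtype=float))
    if centres.size == 0:
        return np.empty(0)
    idx = _centres_to_voxels(centres, cavity.shape, frame)
    edt = ndi.distance_transform_edt(~cavity, sampling=frame.voxel_size_zyx)
    return edt[tuple(idx.T)]


def emigration_fraction(
    centres_um: np.ndarray, gfp_flags: np.ndarray, tube_mask: np.ndarray, frame: EmbryoFrame
) -> float:
    """Fraction of GFP+ centres whose containing voxel lies outside the tube."""
    gfp = np.asarray(gfp_flags, dtype=bool)
    if not gfp.any():
        raise ValueError("no GFP+ centres; emigration fraction undefined")
    centres = np.atleast_2d(np.asarray(centres_um, dtype=float))[gfp]
    idx = _centres_to_voxels(centres, tube_mask.shape, frame)
    inside = np.asarray(tube_mask, dtype=bool)[tuple(idx.T)]
    return float(np.mean(~inside))


def dbscan_clusters(centres_um: np.ndarray, params: ClusterParams = ClusterParams()) -> ClusterResult:
    """DBSCAN on nucleus centres with minPts = minimum emitted cluster size.

    A point counts itself among its eps-neighbours. Any cluster smaller
    than ``min_cluster_size`` (impossible for plain DBSCAN, but enforced as
    a floor) is demoted to noise. Labels are renumbered 0..K-1 in order of
    first appearance so a fixed input ordering gives deterministic labels.
    """
    centres = np.atleast_2d(np.asarray(centres_um, dtype=float))
    if centres.size == 0:
        return ClusterResult(np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0), np.empty(0), None)
    raw = DBSCAN(eps=params.eps_um, min_samples=params.min_cluster_size).fit_predict(centres)
    labels = raw.copy()
    for lab in np.unique(raw[raw >= 0]):
        if np.sum(raw == lab) < params.min_cluster_size:
            labels[raw == lab] = -1
    # renumber in order of first appearance
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out[i] = mapping[lab]
    sizes = np.bincount(out[out >= 0]) if (out >= 0).any() else np.empty(0, dtype=int)
    if sizes.size:
        size_classes, counts = np.unique(sizes, return_counts=True)
        percentages = 100.0 * counts / sizes.size
    else:
        size_classes = np.empty(0, dtype=int)
        percentages = np.empty(0)
    exp_fit = None
    if size_classes.size >= 2:
        exp_fit = fit_cluster_size_distribution(sizes)
    return ClusterResult(out, sizes, size_classes, percentages, exp_fit)


def fit_cluster_size_distribution(sizes: np.ndarray) -> tuple[float, float, float]:
    """Fit % of clusters vs. cluster size to A exp(-k size).

    The percentage of clusters in each realised size class is fitted on the
    log-linear scale by least squares (zero-percentage classes cannot occur
    among realised sizes and are excluded by construction). Returns
    (A, k, rss) with rss the residual sum of squares on the log scale.
    Raises for fewer than two distinct size classes.
    """
    sizes = np.asarray(sizes, dtype=int)
    size_classes, counts = np.unique(sizes, return_counts=True)
    if size_classes.size < 2:
        raise ValueError("need at least two distinct cluster sizes for an exponential fit")
    pct = 100.0 * counts / counts.sum()
    coeffs, residuals, *_ = np.polyfit(size_classes.astype(float), np.log(pct), 1, full=True)
    k = -float(coeffs[0])
    amplitude = float(np.exp(coeffs[1]))
    rss = float(residuals[0]) if residuals.size else 0.0
    return amplitude, k, rss


def nearest_neighbour_distances(centres_um: np.ndarray) -> np.ndarray:
    """Each point's Euclidean distance (um) to its closest other point."""
    centres = np.atleast_2d(np.asarray(centres_um, dtype=float))
    if centres.shape[0] < 2:
        raise ValueError("need at least two points for nearest-neighbour distances")
    tree = cKDTree(centres)
    dists, _ = tree.query(centres, k=2)
    return dists[:, 1]
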