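"""Ellipsoid fits, shape descriptors and nuclear orientation angles.

A segmented nucleus is summarised by the ellipsoid matching its second
moments: for a uniform solid ellipsoid with semi-axes (a, b, c) the
covariance eigenvalues are (a^2/5, b^2/5, c^2/5), so semi-axes are
recovered as sqrt(5 * eigenvalue) along the covariance eigenvectors.
Sheppard's correction (h^2/12 per axis) compensates for voxel-centre
sampling at finite voxel size h.

Shape is reported as prolate ellipticity 2(c-b)/(b+c) (cigar-ness,
0 for a sphere), oblate ellipticity 2(b-a)/(a+b) (pancake-ness) and
sphericity pi^(1/3) (6V)^(2/3) / A with the Knud Thomsen surface-area
approximation.

Orientation of the major axis is expressed in the embryo frame as the
polar angle theta (deviation from the dorso-ventral z axis) and azimuth
phi (within the medial-lateral / antero-posterior plane, 0 = medial-
lateral). An axis is a direction without sign, so vectors are first
folded into the half-space x >= 0, giving theta in [0, 180] and phi in
(-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tubemorph.phantom import EmbryoFrame

__all__ = [
    "EllipsoidFit",
    "ShapeMetrics",
    "OrientationAngles",
    "fit_ellipsoid",
    "shape_metrics",
    "orientation_angles",
]

_KNUD_THOMSEN_P = 1.6075


@dataclass(frozen=True)
class EllipsoidFit:
    """Moment-matched ellipsoid: centre (um), ascending semi-axes (um),
    and orthonormal principal axes as columns (minor, middle, major)."""

    centre_um: np.ndarray
    semi_axes_um: np.ndarray
    principal_axes: np.ndarray

    @property
    def major_axis(self) -> np.ndarray:
        return self.principal_axes[:, 2]


@dataclass(frozen=True)
class ShapeMetrics:
    prolate_ellipticity: float
    oblate_ellipticity: float
    sphericity: float


@dataclass(frozen=True)
class OrientationAngles:
    """theta: degrees from the dorso-ventral z axis, in [0, 180];
    phi: azimuth in the x-y plane, degrees in (-90, 90], 0 = medial-lateral."""

    theta_deg: float
    phi_deg: float


def fit_ellipsoid(
    points_um: np.ndarray, frame: EmbryoFrame, sheppard_correction: bool = True
) -> EllipsoidFit:
    """Fit an ellipsoid to a cloud of voxel-centre points (physical x, y, z).

    Centre = centroid; principal axes = covariance eigenvectors; semi-axis
    lengths = sqrt(5 lambda), valid for points filling a uniform solid
    ellipsoid. With ``sheppard_correction`` the per-axis variance h^2/12
    lost to voxel-centre sampling is restored before the eigendecomposition.

    Raises ``ValueError`` for fewer than 4 points or a degenerate
    (coplanar/collinear) cloud.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if pts.shape[0] < 4:
        raise ValueError(f"need >= 4 points for an ellipsoid fit, got {pts.shape[0]}")
    centre = pts.mean(axis=0)
    d = pts - centre
    cov = d.T @ d / pts.shape[0]
    raw_eigvals = np.linalg.eigvalsh(cov)
    scale = max(float(raw_eigvals[-1]), np.max(np.asarray(frame.voxel_size)) ** 2)
    if raw_eigvals[0] <= 1e-9 * scale:
        raise ValueError("degenerate point cloud: points are coplanar or collinear")
    if sheppard_correction:
        cov = cov + np.diag(np.asarray(frame.voxel_size, dtype=float) ** 2 / 12.0)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    semi = np.sqrt(5.0 * eigvals)
    # right-handed, deterministic sign: largest-magnitude component positive
    for k in range(3):
        v = eigvecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            eigvecs[:, k] = -v
    if np.linalg.det(eigvecs) < 0:
        eigvecs[:, 0] = -eigvecs[:, 0]
    return EllipsoidFit(centre_um=centre, semi_axes_um=semi, principal_axes=eigvecs)


def shape_metrics(fit: EllipsoidFit, voxel_count: int, frame: EmbryoFrame) -> ShapeMetrics:
    """Shape descriptors from a fit plus the object's voxel count.

    Volume is measured (voxel count times voxel volume); surface area comes
    from the fitted semi-axes via the Knud Thomsen approximation, so a
    perfect sphere scores sphericity 1 up to discretisation.
    """
    a, b, c = fit.semi_axes_um
    prolate = 2.0 * (c - b) / (b + c)
    oblate = 2.0 * (b - a) / (a + b)
    volume = float(voxel_count) * float(np.prod(frame.voxel_size))
    p = _KNUD_THOMSEN_P
    area = 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    return ShapeMetrics(float(prolate), float(oblate), float(sphericity))


def orientation_angles(major_axis: np.ndarray, frame: EmbryoFrame) -> OrientationAngles:
    """Polar coordinates of a nuclear major axis in the embryo frame.

    The axis is sign-folded so its x component is >= 0 (ties: y >= 0, then
    z >= 0), making the result invariant under v -> -v. theta is the angle
    to the dorso-ventral z axis; phi the azimuth from the medial-lateral x
    axis within the x-y plane.
    """
    v = np.asarray(major_axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no orientation")
    v = v / n
    if v[0] < 0 or (v[0] == 0 and (v[1] < 0 or (v[1] == 0 and v[2] < 0))):
        v = -v
    v = v + 0.0  # clear negative zeros so atan2(0, 0) stays at 0
    theta = np.degrees(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(v[1], v[0]))
    return OrientationAngles(float(theta), float(phi))
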