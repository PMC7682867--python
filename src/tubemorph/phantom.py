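"""Synthetic embryo phantoms and synthetic DNA-content event tables.

The phantom emulates a transverse block of the embryonic neural tube: a
half-cylindrical epithelial slab whose apical face borders a thin slit
lumen (the neural cavity), surrounded by "mesodermal" space. Nuclei are
solid ellipsoids rendered into a multi-channel voxel stack (DNA stain,
nuclear GFP electroporation marker, optional extra markers such as an
EdU-like channel), together with binary tube/cavity masks and a
ground-truth table — so every downstream measurement can be checked
against what was actually drawn.

Two tissue states are modelled:

* ``epithelial`` — elongated nuclei with major axes along the
  medial-lateral (x) axis up to a small angular jitter, all confined to
  the tube, as in a pseudostratified neuroepithelium;
* ``mesenchymal`` — the transformed state: orientations uniform on the
  sphere, a per-nucleus probability of having emigrated beyond the tube
  boundary, and optional seeded clusters of mutually close cells.

Microscope-like degradations (Gaussian blur, additive noise, per-slice
depth attenuation, small saturated debris objects) are applied after the
ground truth is frozen.

Axis conventions: arrays are indexed ``[z, y, x]`` (channel-first
``[c, z, y, x]`` for multi-channel stacks); physical axes are
x = medial-lateral, y = antero-posterior, z = dorso-ventral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from tubemorph._rng import substream

__all__ = [
    "EmbryoFrame",
    "ClusterSpec",
    "PhantomConfig",
    "TissuePhantom",
    "generate_phantom",
    "simulate_dna_events",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclass(frozen=True)
class EmbryoFrame:
    """Physical coordinate frame of the embryo volume.

    x is the medial-lateral direction, y antero-posterior, z dorso-ventral.
    Physical coordinates are ``voxel index * voxel_size + origin`` with
    0-based indices and the voxel-centre convention.

    Parameters
    ----------
    voxel_size
        Micrometres per voxel along (x, y, z). Isotropic by default.
    origin
        Physical coordinate (x, y, z) of voxel (0, 0, 0), in um.
    """

    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not all(v > 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        vx, vy, vz = self.voxel_size
        return (vz, vy, vx)

    def to_physical(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Voxel indices (..., 3) in zyx order -> physical (x, y, z) um."""
        idx = np.asarray(indices_zyx, dtype=float)
        xyz = idx[..., ::-1]
        return xyz * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def to_voxel(self, points_xyz: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) um -> nearest voxel indices (..., 3) zyx."""
        p = np.asarray(points_xyz, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / np.asarray(self.voxel_size))
        return idx[..., ::-1].astype(int)


@dataclass(frozen=True)
class ClusterSpec:
    """Seeded cell clusters for the mesenchymal state.

    ``n_clusters`` chains of ``cluster_size`` nuclei are placed so that each
    member lies within ``spread_um`` of another member (chain connectivity),
    while keeping the global minimum nucleus separation.
    """

    n_clusters: int = 5
    cluster_size: int = 5
    spread_um: float = 9.0

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.cluster_size < 1:
            raise ValueError("cluster_spec requires n_clusters >= 0 and cluster_size >= 1")
        if self.spread_um <= 0:
            raise ValueError("cluster spread_um must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one rendered tissue state.

    Attributes
    ----------
    state
        ``"epithelial"`` or ``"mesenchymal"``.
    n_nuclei
        Number of ground-truth nuclei.
    semi_axes_um
        Ground-truth ellipsoid semi-axes (a, b, c) in um, a <= b <= c.
    orientation_noise_deg
        S.d. of the angular jitter around the medial-lateral axis
        (epithelial state only).
    emigration_prob
        Per-nucleus probability of placement outside the tube
        (mesenchymal state only).
    cluster_spec
        Seeded clusters (mesenchymal state only), or None.
    gfp_prob
        Probability that a nucleus is GFP+ (electroporated).
    marker_probs
        Positivity probability per extra marker channel, among GFP+ nuclei.
    volume_um
        Physical extent (X, Y, Z) of the rendered block, in um.
    tube_radius_um, cavity_width_um
        Geometry of the half-cylinder tube and the apical slit lumen.
    min_separation_um
        Minimum distance between nucleus centres during placement.
    noise_sd
        Additive Gaussian image noise s.d. (intensity units).
    attenuation_per_slice
        Multiplicative intensity decay per z-slice (1.0 = none).
    n_debris
        Number of small saturated debris blobs (each < 95 voxels at the
        default voxel size).
    seed
        Root RNG seed; same (config, frame) and seed give bit-identical
        truth tables and images.
    """

    state: str = "epithelial"
    n_nuclei: int = 100
    semi_axes_um: tuple[float, float, float] = (2.0, 2.0, 3.0)
    orientation_noise_deg: float = 5.0
    emigration_prob: float = 0.0
    cluster_spec: ClusterSpec | None = None
    gfp_prob: float = 1.0
    marker_probs: dict[str, float] = field(default_factory=dict)
    volume_um: tuple[float, float, float] = (80.0, 100.0, 50.0)
    tube_radius_um: float = 40.0
    cavity_width_um: float = 3.0
    min_separation_um: float = 7.0
    nucleus_intensity: float = 200.0
    marker_intensity: float = 150.0
    dynamic_max: float = 255.0
    blur_sigma_um: float = 0.4
    noise_sd: float = 4.0
    attenuation_per_slice: float = 1.0
    n_debris: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in ("epithelial", "mesenchymal"):
            raise ValueError(f"state must be 'epithelial' or 'mesenchymal', got {self.state!r}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        a, b, c = self.semi_axes_um
        if not (0 < a <= b <= c):
            raise ValueError(f"semi_axes_um must be positive and ordered a <= b <= c, got {self.semi_axes_um}")
        for name, p in [("emigration_prob", self.emigration_prob), ("gfp_prob", self.gfp_prob)] + [
            (f"marker_probs[{k}]", v) for k, v in self.marker_probs.items()
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.orientation_noise_deg < 0:
            raise ValueError("orientation_noise_deg must be >= 0")
        if self.noise_sd < 0 or self.n_debris < 0:
            raise ValueError("noise_sd and n_debris must be >= 0")
        if not 0 < self.attenuation_per_slice <= 1.0:
            raise ValueError("attenuation_per_slice must be in (0, 1]")
        if self.cavity_width_um >= self.tube_radius_um:
            raise ValueError("cavity must be thinner than the tube radius")


@dataclass
class TissuePhantom:
    """A rendered phantom: image channels, masks, frame, and ground truth.

    ``image`` has axis order (channel, z, y, x); ``channel_names`` gives the
    channel labels ("dna", "gfp", then any extra markers). ``truth`` is a
    DataFrame with one row per ground-truth nucleus: centre and major-axis
    components in um, compartment, GFP/marker flags and seeded cluster id
    (-1 for none).
    """

    image: np.ndarray
    channel_names: list[str]
    tube_mask: np.ndarray
    cavity_mask: np.ndarray
    frame: EmbryoFrame
    truth: pd.DataFrame
    config: PhantomConfig

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {name: self.image[i] for i, name in enumerate(self.channel_names)}


# ---------------------------------------------------------------------------
# geometry helpers


def _volume_shape(config: PhantomConfig, frame: EmbryoFrame) -> tuple[int, int, int]:
    X, Y, Z = config.volume_um
    vx, vy, vz = frame.voxel_size
    return (int(round(Z / vz)), int(round(Y / vy)), int(round(X / vx)))


def _make_masks(config: PhantomConfig, frame: EmbryoFrame, shape_zyx: tuple[int, int, int]):
    """Half-cylinder tube (axis along y at the medial face) + slit cavity."""
    nz, ny, nx = shape_zyx
    vx, vy, vz = frame.voxel_size
    x = np.arange(nx) * vx + frame.origin[0]
    z = np.arange(nz) * vz + frame.origin[2]
    zc = config.volume_um[2] / 2.0
    xx = x[np.newaxis, :]
    zz = (z - zc)[:, np.newaxis]
    r2 = xx**2 + zz**2  # (nz, nx)
    in_tube_zx = (r2 <= config.tube_radius_um**2) & (xx >= 0)
    cavity_zx = in_tube_zx & (xx < config.cavity_width_um)
    tube = np.broadcast_to(in_tube_zx[:, np.newaxis, :], (nz, ny, nx)).copy()
    cavity = np.broadcast_to(cavity_zx[:, np.newaxis, :], (nz, ny, nx)).copy()
    return tube, cavity


def _radial2(p: np.ndarray, config: PhantomConfig) -> float:
    zc = config.volume_um[2] / 2.0
    return p[0] ** 2 + (p[2] - zc) ** 2


def _in_tube_region(p: np.ndarray, config: PhantomConfig, margin: float) -> bool:
    """Centre strictly inside the tube, clear of cavity and tube boundary."""
    ok_radial = _radial2(p, config) <= (config.tube_radius_um - margin) ** 2
    return bool(ok_radial and p[0] >= config.cavity_width_um + margin)


def _in_mesenchyme(p: np.ndarray, config: PhantomConfig, margin: float) -> bool:
    return bool(_radial2(p, config) >= (config.tube_radius_um + margin) ** 2)


def _sample_point(rng: np.random.Generator, config: PhantomConfig, margin: float) -> np.ndarray:
    X, Y, Z = config.volume_um
    lo = np.array([margin, margin, margin])
    hi = np.array([X - margin, Y - margin, Z - margin])
    return rng.uniform(lo, hi)


def _place_centres(rng: np.random.Generator, config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (centres_xyz, emigrated_flags, cluster_ids)."""
    n = config.n_nuclei
    c_major = config.semi_axes_um[2]
    margin = c_major + 1.0
    min_sep = config.min_separation_um

    if config.state == "mesenchymal" and config.emigration_prob > 0:
        # single documented draw so the binomial count is replayable
        emigrated = substream(config.seed, "emigration").random(n) < config.emigration_prob
    else:
        emigrated = np.zeros(n, dtype=bool)

    cluster_ids = np.full(n, -1, dtype=int)
    spec = config.cluster_spec if config.state == "mesenchymal" else None
    if spec is not None and spec.n_clusters > 0:
        in_tube_idx = np.flatnonzero(~emigrated)
        needed = spec.n_clusters * spec.cluster_size
        if needed > in_tube_idx.size:
            raise PlacementError(
                f"cluster_spec needs {needed} in-tube nuclei but only {in_tube_idx.size} are available"
            )
        for k in range(spec.n_clusters):
            members = in_tube_idx[k * spec.cluster_size : (k + 1) * spec.cluster_size]
            cluster_ids[members] = k

    # physical contact limit: two nuclei cannot overlap even inside a cluster
    contact = 2.0 * c_major + 0.8
    if spec is not None and spec.n_clusters > 0 and spec.spread_um <= contact:
        raise PlacementError(
            f"cluster spread {spec.spread_um} um is not above the nucleus contact distance {contact:.1f} um"
        )

    centres = np.full((n, 3), np.nan)
    placed = np.empty((n, 3))
    n_placed = 0

    def _accept(p: np.ndarray, sep: float) -> bool:
        if n_placed and np.min(np.sum((placed[:n_placed] - p) ** 2, axis=1)) < sep**2:
            return False
        return True

    max_attempts = 400 * max(n, 1)
    attempts = 0

    def _draw(region_ok, near: np.ndarray | None = None, rmax: float | None = None) -> np.ndarray:
        nonlocal attempts
        sep = contact if near is not None else min_sep
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {n} nuclei with min separation {min_sep} um in volume "
                    f"{config.volume_um} um after {max_attempts} attempts; reduce density"
                )
            if near is not None:
                # chain placement: within (contact, rmax] of an existing member
                d = rng.uniform(contact, rmax)
                u = rng.normal(size=3)
                p = near + d * u / np.linalg.norm(u)
            else:
                p = _sample_point(rng, config, margin)
            X, Y, Z = config.volume_um
            if not np.all((p >= margin) & (p <= np.array([X, Y, Z]) - margin)):
                continue
            if region_ok(p) and _accept(p, sep):
                return p

    def _commit(i: int, p: np.ndarray) -> None:
        nonlocal n_placed
        centres[i] = p
        placed[n_placed] = p
        n_placed += 1

    # clusters first (chains are the hardest to place)
    if spec is not None and spec.n_clusters > 0:
        for k in range(spec.n_clusters):
            members = np.flatnonzero(cluster_ids == k)
            anchor = _draw(lambda p: _in_tube_region(p, config, margin))
            _commit(members[0], anchor)
            chain = [anchor]
            for m in members[1:]:
                prev = chain[rng.integers(len(chain))]
                p = _draw(lambda q: _in_tube_region(q, config, margin), near=prev, rmax=spec.spread_um)
                _commit(m, p)
                chain.append(p)

    for i in range(n):
        if not np.isnan(centres[i, 0]):
            continue
        if emigrated[i]:
            p = _draw(lambda q: _in_mesenchyme(q, config, 1.0))
        else:
            p = _draw(lambda q: _in_tube_region(q, config, margin))
        _commit(i, p)

    return centres, emigrated, cluster_ids


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _draw_orientations(rng: np.random.Generator, config: PhantomConfig) -> np.ndarray:
    """Major-axis unit vectors, one per nucleus."""
    n = config.n_nuclei
    axes = np.empty((n, 3))
    if config.state == "epithelial":
        sigma = np.deg2rad(config.orientation_noise_deg)
        target = np.array([1.0, 0.0, 0.0])
        for i in range(n):
            angle = abs(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
            k = _unit(rng.normal(size=3))  # rotation axis, uniform on the sphere
            # Rodrigues rotation of the medial-lateral axis
            v = (
                target * np.cos(angle)
                + np.cross(k, target) * np.sin(angle)
                + k * np.dot(k, target) * (1 - np.cos(angle))
            )
            axes[i] = _unit(v)
    else:
        for i in range(n):
            axes[i] = _unit(rng.normal(size=3))
    return axes


def _orthonormal_frame(major: np.ndarray) -> np.ndarray:
    """Columns = (minor, middle, major) unit vectors."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, major)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    middle = _unit(np.cross(major, helper))
    minor = np.cross(middle, major)
    return np.column_stack([minor, middle, major])


def _render_ellipsoid(
    volume: np.ndarray, frame: EmbryoFrame, centre: np.ndarray, semi_axes: np.ndarray, rot: np.ndarray, value: float
) -> None:
    """Paint a solid ellipsoid into `volume` (zyx) at physical `centre`."""
    vx, vy, vz = frame.voxel_size
    c_major = semi_axes[2]
    lo = frame.to_voxel(centre - c_major - 1.0)
    hi = frame.to_voxel(centre + c_major + 1.0) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, volume.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
    pts = np.stack(
        [xx * vx + frame.origin[0], yy * vy + frame.origin[1], zz * vz + frame.origin[2]], axis=-1
    ) - centre
    local = pts @ rot  # components along (minor, middle, major)
    inside = np.sum((local / semi_axes) ** 2, axis=-1) <= 1.0
    sub = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[inside] = value


def generate_phantom(config: PhantomConfig, frame: EmbryoFrame | None = None) -> TissuePhantom:
    """Render a synthetic embryo block with ground truth.

    The truth table is frozen before rendering; blur, debris, per-slice
    attenuation and additive noise are applied afterwards, in that order,
    and the image is clipped to ``[0, dynamic_max]`` so debris voxels sit
    at the saturation value.
    """
    if frame is None:
        frame = EmbryoFrame()
    shape = _volume_shape(config, frame)
    tube_mask, cavity_mask = _make_masks(config, frame, shape)

    rng_place = substream(config.seed, "placement")
    rng_orient = substream(config.seed, "orientation")
    rng_marker = substream(config.seed, "markers")
    rng_noise = substream(config.seed, "noise")
    rng_debris = substream(config.seed, "debris")

    n = config.n_nuclei
    centres, emigrated, cluster_ids = _place_centres(rng_place, config)
    majors = _draw_orientations(rng_orient, config)
    gfp = rng_marker.random(n) < config.gfp_prob
    marker_names = sorted(config.marker_probs)
    marker_flags = {m: gfp & (rng_marker.random(n) < config.marker_probs[m]) for m in marker_names}

    compartment = np.where(emigrated, "emigrated", "in_tube")
    if n:
        centre_vox = frame.to_voxel(centres)
        in_cavity = cavity_mask[tuple(centre_vox.T)]
        compartment = np.where(in_cavity, "lumen", compartment)

    truth = pd.DataFrame(
        {
            "id": np.arange(n),
            "x_um": centres[:, 0] if n else np.array([]),
            "y_um": centres[:, 1] if n else np.array([]),
            "z_um": centres[:, 2] if n else np.array([]),
            "semi_a_um": np.full(n, config.semi_axes_um[0]),
            "semi_b_um": np.full(n, config.semi_axes_um[1]),
            "semi_c_um": np.full(n, config.semi_axes_um[2]),
            "major_x": majors[:, 0] if n else np.array([]),
            "major_y": majors[:, 1] if n else np.array([]),
            "major_z": majors[:, 2] if n else np.array([]),
            "compartment": compartment if n else np.array([], dtype=object),
            "gfp_positive": gfp.astype(int),
            "cluster_id": cluster_ids,
        }
    )
    for m in marker_names:
        truth[f"{m}_positive"] = marker_flags[m].astype(int)

    channel_names = ["dna", "gfp"] + marker_names
    image = np.zeros((len(channel_names),) + shape, dtype=np.float32)
    semi = np.asarray(config.semi_axes_um)
    for i in range(n):
        rot = _orthonormal_frame(majors[i])
        _render_ellipsoid(image[0], frame, centres[i], semi, rot, config.nucleus_intensity)
        if gfp[i]:
            _render_ellipsoid(image[1], frame, centres[i], semi, rot, config.marker_intensity)
        for j, m in enumerate(marker_names):
            if marker_flags[m][i]:
                _render_ellipsoid(image[2 + j], frame, centres[i], semi, rot, config.marker_intensity)

    if config.blur_sigma_um > 0:
        sig = [config.blur_sigma_um / s for s in frame.voxel_size_zyx]
        for c in range(image.shape[0]):
            image[c] = ndi.gaussian_filter(image[c], sigma=sig)

    # saturated debris: small blobs painted above the dynamic range so they
    # clip to the maximum even after attenuation
    for _ in range(config.n_debris):
        for _attempt in range(1000):
            p = _sample_point(rng_debris, config, 2.0)
            if n == 0 or np.min(np.linalg.norm(centres - p, axis=1)) > semi[2] + 3.0:
                break
        r = rng_debris.uniform(0.8, 1.3)
        _render_ellipsoid(image[0], frame, p, np.array([r, r, r]), np.eye(3), 2.0 * config.dynamic_max)

    if config.attenuation_per_slice < 1.0:
        gain = config.attenuation_per_slice ** np.arange(shape[0], dtype=np.float64)
        image *= gain[np.newaxis, :, np.newaxis, np.newaxis].astype(np.float32)

    if config.noise_sd > 0:
        image += rng_noise.normal(0.0, config.noise_sd, size=image.shape).astype(np.float32)

    np.clip(image, 0.0, config.dynamic_max, out=image)

    return TissuePhantom(
        image=image,
        channel_names=channel_names,
        tube_mask=tube_mask,
        cavity_mask=cavity_mask,
        frame=frame,
        truth=truth,
        config=config,
    )


def epithelial_preset(**overrides) -> PhantomConfig:
    """Control-tissue condition: elongated nuclei (2, 2, 3) um aligned to the
    medial-lateral axis with 5 deg jitter, all confined to the tube."""
    base = dict(
        state="epithelial",
        n_nuclei=200,
        semi_axes_um=(2.0, 2.0, 3.0),
        orientation_noise_deg=5.0,
        volume_um=(80.0, 160.0, 50.0),
        noise_sd=2.0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def mesenchymal_preset(**overrides) -> PhantomConfig:
    """Transformed condition: rounder nuclei, random orientations, 20%
    emigration beyond the tube, seeded clusters of mutually close cells."""
    base = dict(
        state="mesenchymal",
        n_nuclei=500,
        semi_axes_um=(2.0, 2.2, 2.6),
        emigration_prob=0.2,
        cluster_spec=ClusterSpec(n_clusters=8, cluster_size=5, spread_um=9.0),
        volume_um=(100.0, 200.0, 50.0),
        noise_sd=2.0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def simulate_dna_events(
    n: int,
    fractions: tuple[float, float, float],
    g1_mean: float = 100.0,
    cv: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a pre-gated univariate DNA-content event table.

    Each event gets a true phase drawn from ``fractions = (g1, s, g2m)``.
    G0/G1 content is ``g1_mean``; G2/M is ``2 * g1_mean``; S-phase true
    content is uniform between the two (flat-S assumption). The measured
    fluorescence adds relative Gaussian noise of coefficient of variation
    ``cv`` around the true content.

    Returns a DataFrame with columns ``phase`` ("G1"/"S"/"G2M"),
    ``true_content`` and ``dna_content``.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr < 0):
        raise ValueError("fractions must be three non-negative numbers (g1, s, g2m)")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 within 1e-9, got sum {fr.sum()!r}")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")

    rng = substream(seed, "dna_events")
    phases = np.array(["G1", "S", "G2M"])
    labels = rng.choice(3, size=n, p=fr)
    true_content = np.empty(n)
    true_content[labels == 0] = g1_mean
    true_content[labels == 2] = 2.0 * g1_mean
    n_s = int(np.sum(labels == 1))
    true_content[labels == 1] = rng.uniform(g1_mean, 2.0 * g1_mean, size=n_s)
    measured = rng.normal(true_content, cv * true_content) if n else np.array([])
    return pd.DataFrame({"phase": phases[labels], "true_content": true_content, "dna_content": measured})
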