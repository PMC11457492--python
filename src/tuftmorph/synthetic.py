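"""Seeded synthetic-data generators with known ground truth.

Three families of inputs are emulated so that every downstream stage of the
pipeline can be validated against exact truth:

* 2D cross-sections of filament bundles — jittered hexagonal (or square, or
  completely spatially random) point lattices inside a circular bundle,
  rendered as Gaussian blobs on an EM-like background;
* two-channel 3D volumes of near-vertical, optionally co-aligned polymers
  (actin bundles and microtubules);
* 1D intensity profiles drawn from the fit models used for linescan
  regionalization (lognormal, sigmoidal 4PL, quartic, exponential decay).

Defaults follow the tuft-cell measurements the pipeline is built to analyse:
9.2 nm filament spacing, 53 nm bundle radius (106 nm diameter), polymer pitch
centred on 81.1 degrees, lengths 5-12 um.

Polymers are straight segments: the pitch and interaction statistics the
pipeline computes depend only on direction and length, not curvature.
Vacancies are i.i.d. removals (isolated missing filaments, not correlated
dislocation lines). Noise is additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line_nd

from .core import ImagePlane, LineProfile, PointSet, VolumeMask
from .models import MODEL_ARITY, evaluate_model

__all__ = [
    "LatticeSpec", "RenderSpec", "Network3DSpec", "ProfileSpec",
    "gen_lattice_points", "render_cross_section", "gen_network_volume",
    "gen_profile",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a synthetic filament-centre point pattern.

    ``bundle_radius_nm`` bounds the centres: every generated point lies within
    that distance of the bundle centre. ``csr`` mode ignores spacing/jitter and
    places ``n_points`` uniformly on the disc (the negative control for
    lattice order).
    """

    lattice_kind: str = "hex"        # hex | square | csr
    spacing_nm: float = 9.2          # nearest-neighbour centre-to-centre d
    jitter_sd_nm: float = 0.0        # isotropic Gaussian positional jitter
    vacancy_fraction: float = 0.0    # i.i.d. removal probability
    bundle_radius_nm: float = 53.0
    n_points: int | None = None      # csr only
    center_nm: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_kind not in ("hex", "square", "csr"):
            raise ValueError(f"unknown lattice_kind {self.lattice_kind!r}")
        if self.lattice_kind != "csr" and self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be positive")
        if not 0 <= self.vacancy_fraction < 1:
            raise ValueError("vacancy_fraction must be in [0, 1)")
        if self.jitter_sd_nm < 0:
            raise ValueError("jitter_sd_nm must be nonnegative")
        if self.bundle_radius_nm <= 0:
            raise ValueError("bundle_radius_nm must be positive")
        if self.lattice_kind == "csr" and (self.n_points is None
                                           or self.n_points <= 0):
            raise ValueError("csr mode requires a positive n_points")


@dataclass(frozen=True)
class RenderSpec:
    """How a point pattern is rasterized into an EM-like image."""

    pixel_size_nm: float = 1.0
    psf_sigma_nm: float = 2.0        # Gaussian blob sd per filament
    noise_sd: float = 0.0            # additive Gaussian, intensity units
    polarity: str = "dark_filaments"  # dark_filaments | bright_filaments
    image_shape_px: tuple[int, int] = (256, 256)
    background_level: float = 0.75
    blob_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_nm and noise_sd must be nonnegative")
        if self.polarity not in ("dark_filaments", "bright_filaments"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if min(self.image_shape_px) <= 0:
            raise ValueError("image_shape_px must be positive")


@dataclass(frozen=True)
class Network3DSpec:
    """Two-channel 3D network of straight polymers.

    Pitch is measured from the xy (apical) plane: 90 deg = vertical, i.e.
    parallel to the apicobasal z axis. ``paired_fraction`` of the microtubules
    copy an actin partner's direction at a fixed lateral offset; the rest are
    drawn independently.
    """

    volume_shape_vox: tuple[int, int, int] = (130, 160, 160)  # (z, y, x)
    voxel_size_nm: tuple[float, float, float] = (100.0, 100.0, 100.0)  # (x,y,z)
    n_actin: int = 50
    n_mt: int = 50
    pitch_mean_deg: float = 81.1
    pitch_sd_deg: float = 5.0
    length_um_range: tuple[float, float] = (5.0, 12.0)
    paired_fraction: float = 0.0
    pair_offset_nm: float = 200.0
    min_separation: bool = True   # polymers of one channel never touch
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_actin <= 0 or self.n_mt < 0:
            raise ValueError("need n_actin > 0 and n_mt >= 0")
        if not 0 < self.pitch_mean_deg <= 90:
            raise ValueError("pitch_mean_deg must be in (0, 90]")
        if self.pitch_sd_deg < 0:
            raise ValueError("pitch_sd_deg must be nonnegative")
        lo, hi = self.length_um_range
        if not 1.0 <= lo <= hi <= 15.0:
            raise ValueError("length_um_range must lie within [1, 15] um")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.pair_offset_nm <= 0:
            raise ValueError("pair_offset_nm must be positive")
        # volume must be able to contain the longest polymer at the
        # steepest plausible pitch
        nz, ny, nx = self.volume_shape_vox
        sx, sy, sz = self.voxel_size_nm
        if hi * 1000.0 > np.linalg.norm([nx * sx, ny * sy, nz * sz]):
            raise ValueError("volume too small for maximal polymer length")


@dataclass(frozen=True)
class ProfileSpec:
    """A noisy sample from one of the linescan fit models."""

    model: str = "lognormal"
    params: tuple = (1.0, 1.5, 0.5)
    axis_length_um: float = 7.0
    n_samples: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_ARITY:
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.params) != MODEL_ARITY[self.model]:
            raise ValueError(
                f"{self.model} takes {MODEL_ARITY[self.model]} params, "
                f"got {len(self.params)}")
        if self.axis_length_um <= 0:
            raise ValueError("axis_length_um must be positive")
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# point patterns

def _lattice_sites(kind: str, d: float, radius: float) -> np.ndarray:
    """Enumerate ideal lattice sites within ``radius`` of the origin."""
    if kind == "hex":
        row_h = d * np.sqrt(3) / 2
        jmax = int(np.ceil(radius / row_h)) + 1
        imax = int(np.ceil(radius / d)) + 1
        pts = []
        for j in range(-jmax, jmax + 1):
            y = j * row_h
            xoff = 0.5 * d if j % 2 else 0.0
            for i in range(-imax, imax + 1):
                x = i * d + xoff
                if x * x + y * y <= radius * radius + 1e-9:
                    pts.append((x, y))
        return np.array(pts, dtype=float)
    if kind == "square":
        imax = int(np.ceil(radius / d)) + 1
        ii, jj = np.meshgrid(np.arange(-imax, imax + 1),
                             np.arange(-imax, imax + 1))
        xy = np.column_stack([ii.ravel() * d, jj.ravel() * d]).astype(float)
        return xy[np.einsum("ij,ij->i", xy, xy) <= radius * radius + 1e-9]
    raise ValueError(kind)


def gen_lattice_points(spec: LatticeSpec) -> tuple[PointSet, pd.DataFrame]:
    """Generate a filament-centre point pattern plus its ground-truth table.

    hex/square: ideal lattice sites inside the bundle disc, displaced by
    N(0, jitter_sd^2) per axis, then removed i.i.d. with probability
    ``vacancy_fraction``. csr: ``n_points`` uniform on the disc. Identical
    specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.center_nm
    if spec.lattice_kind == "csr":
        u = rng.random(spec.n_points)
        theta = rng.uniform(0, 2 * np.pi, spec.n_points)
        r = spec.bundle_radius_nm * np.sqrt(u)
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    else:
        xy = _lattice_sites(spec.lattice_kind, spec.spacing_nm,
                            spec.bundle_radius_nm)
        # deterministic ordering independent of enumeration details
        order = np.lexsort((xy[:, 0], xy[:, 1]))
        xy = xy[order]
        if spec.jitter_sd_nm > 0:
            xy = xy + rng.normal(0.0, spec.jitter_sd_nm, size=xy.shape)
        if spec.vacancy_fraction > 0:
            xy = xy[rng.random(len(xy)) >= spec.vacancy_fraction]
    xy = xy + [cx, cy]
    ids = np.arange(len(xy))
    truth = pd.DataFrame({"id": ids, "x_nm": xy[:, 0], "y_nm": xy[:, 1]})
    return PointSet(ids, xy), truth


# ---------------------------------------------------------------------------
# rendering

def render_cross_section(points: PointSet, render: RenderSpec) -> ImagePlane:
    """Rasterize a point pattern as Gaussian blobs on a flat background.

    Dark polarity (TEM-like): blobs subtract from the background; bright
    polarity adds. Intensities are clipped to [0, 1]. The sample at array
    index (r, c) sits at physical position ((c + 0.5), (r + 0.5)) * pixel
    size, matching the half-open pixel convention.
    """
    px = render.pixel_size_nm
    h, w = render.image_shape_px
    coords_px = points.coords_nm / px  # continuous, corner origin
    if len(points):
        bad = np.where((coords_px[:, 0] < 0) | (coords_px[:, 0] >= w)
                       | (coords_px[:, 1] < 0) | (coords_px[:, 1] >= h))[0]
        if bad.size:
            raise ValueError(
                "points outside the field of view: ids "
                f"{points.ids[bad].tolist()}")
    blobs = np.zeros((h, w), dtype=float)
    sigma_px = render.psf_sigma_nm / px
    if len(points):
        # 9 sigma keeps the truncated tail below machine epsilon
        reach = max(1, int(np.ceil(9 * max(sigma_px, 0.5))))
        for x, y in coords_px:
            # sample centres are at index + 0.5
            c0, c1 = max(0, int(x - reach)), min(w, int(x + reach) + 1)
            r0, r1 = max(0, int(y - reach)), min(h, int(y + reach) + 1)
            cc = np.arange(c0, c1) + 0.5
            rr = np.arange(r0, r1) + 0.5
            if sigma_px > 0:
                gx = np.exp(-((cc - x) ** 2) / (2 * sigma_px ** 2))
                gy = np.exp(-((rr - y) ** 2) / (2 * sigma_px ** 2))
                blobs[r0:r1, c0:c1] += np.outer(gy, gx)
            else:  # delta blob: nearest sample
                blobs[min(h - 1, int(y)), min(w - 1, int(x))] += 1.0
    sign = -1.0 if render.polarity == "dark_filaments" else 1.0
    img = render.background_level + sign * render.blob_amplitude * blobs
    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
    return ImagePlane(np.clip(img, 0.0, 1.0), px)


# ---------------------------------------------------------------------------
# 3D networks

def _direction_from_pitch(pitch_deg: float, azimuth_rad: float) -> np.ndarray:
    """Unit direction (x, y, z) with inclination ``pitch_deg`` above the
    xy-plane; z positive (descending from the apical surface)."""
    p = np.deg2rad(pitch_deg)
    return np.array([np.cos(p) * np.cos(azimuth_rad),
                     np.cos(p) * np.sin(azimuth_rad),
                     np.sin(p)])


def _truncated_pitch(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        p = rng.normal(mean, sd)
        if 0 < p <= 90:
            return p
    raise RuntimeError("pitch sampling failed (degenerate spec)")


def _rasterize_segment(start_nm: np.ndarray, end_nm: np.ndarray,
                       shape_zyx: tuple[int, int, int],
                       voxel_xyz: tuple[float, float, float]) -> tuple:
    sx, sy, sz = voxel_xyz
    s_vox = np.array([start_nm[2] / sz, start_nm[1] / sy, start_nm[0] / sx])
    e_vox = np.array([end_nm[2] / sz, end_nm[1] / sy, end_nm[0] / sx])
    idx = line_nd(s_vox, e_vox, endpoint=True)
    # endpoints inside the volume can still round onto the boundary voxel
    return tuple(np.clip(ax, 0, n - 1)
                 for ax, n in zip(idx, shape_zyx))


def gen_network_volume(
    spec: Network3DSpec,
) -> tuple[VolumeMask, VolumeMask, pd.DataFrame]:
    """Generate actin and microtubule channels plus an exact truth table.

    Each polymer is a straight voxel line. Pitch is N(pitch_mean, pitch_sd)
    truncated to (0, 90], azimuth uniform, length uniform on
    ``length_um_range``. The first ``round(paired_fraction * n_mt)``
    microtubules copy the direction of actin partner i, displaced laterally
    (perpendicular to the shared direction) by ``pair_offset_nm``. Endpoints
    are resampled up to ``max_retries`` times if a polymer exits the volume;
    silent truncation would bias the length truth.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.volume_shape_vox
    sx, sy, sz = spec.voxel_size_nm
    extent = np.array([nx * sx, ny * sy, nz * sz])  # nm, (x, y, z)
    shape = (nz, ny, nx)
    # offsets covering the 26-neighbourhood, for the separation check
    nb = np.array([o for o in np.ndindex(3, 3, 3)]) - 1

    def touches(channel: np.ndarray, idx: tuple) -> bool:
        """True if the candidate line is 26-adjacent to existing voxels."""
        pts = np.stack(idx, axis=1)[:, None, :] + nb[None, :, :]
        pts = pts.reshape(-1, 3)
        np.clip(pts, 0, np.array(shape) - 1, out=pts)
        return bool(channel[pts[:, 0], pts[:, 1], pts[:, 2]].any())

    def place_free(channel: np.ndarray, direction: np.ndarray,
                   length_nm: float) -> tuple:
        for _ in range(spec.max_retries):
            start = rng.random(3) * extent
            end = start + direction * length_nm
            if not (np.all((end >= 0) & (end < extent))
                    and np.all((start >= 0) & (start < extent))):
                continue
            idx = _rasterize_segment(start, end, shape, spec.voxel_size_nm)
            if spec.min_separation and touches(channel, idx):
                continue
            return start, end, idx
        raise RuntimeError("could not place polymer after retry cap; "
                           "enlarge the volume or shorten polymers")

    actin_vox = np.zeros(shape, dtype=bool)
    mt_vox = np.zeros(shape, dtype=bool)
    rows = []
    actin_info = []  # (start, direction, length_nm)
    for i in range(spec.n_actin):
        pitch = _truncated_pitch(rng, spec.pitch_mean_deg, spec.pitch_sd_deg)
        az = rng.uniform(0, 2 * np.pi)
        length_nm = rng.uniform(*spec.length_um_range) * 1000.0
        direction = _direction_from_pitch(pitch, az)
        start, end, idx = place_free(actin_vox, direction, length_nm)
        actin_vox[idx] = True
        actin_info.append((start, direction, length_nm))
        rows.append(dict(id=i, channel="actin", pitch_deg=pitch,
                         length_um=length_nm / 1000.0, paired_with=-1,
                         x0_nm=start[0], y0_nm=start[1], z0_nm=start[2],
                         x1_nm=end[0], y1_nm=end[1], z1_nm=end[2]))

    n_paired = int(round(spec.paired_fraction * spec.n_mt))
    for j in range(spec.n_mt):
        mid = spec.n_actin + j
        if j < n_paired:
            partner = j % spec.n_actin
            p_start, direction, p_len = actin_info[partner]
            placed = None
            for _ in range(spec.max_retries):
                # lateral offset perpendicular to the shared direction
                phi = rng.uniform(0, 2 * np.pi)
                ref = np.array([0.0, 0.0, 1.0])
                if abs(direction[2]) > 0.99:
                    ref = np.array([1.0, 0.0, 0.0])
                u = np.cross(direction, ref)
                u /= np.linalg.norm(u)
                v = np.cross(direction, u)
                offset = spec.pair_offset_nm * (np.cos(phi) * u
                                                + np.sin(phi) * v)
                start = p_start + offset
                end = start + direction * p_len
                if not (np.all((end >= 0) & (end < extent))
                        and np.all((start >= 0) & (start < extent))):
                    continue
                idx = _rasterize_segment(start, end, shape,
                                         spec.voxel_size_nm)
                if spec.min_separation and touches(mt_vox, idx):
                    continue
                placed = (start, end, idx)
                break
            if placed is None:
                raise RuntimeError("paired microtubule could not be placed "
                                   "after retry cap")
            start, end, idx = placed
            pitch = float(np.rad2deg(np.arcsin(abs(direction[2]))))
            length_nm = p_len
            paired_with = partner
        else:
            pitch = _truncated_pitch(rng, spec.pitch_mean_deg,
                                     spec.pitch_sd_deg)
            az = rng.uniform(0, 2 * np.pi)
            length_nm = rng.uniform(*spec.length_um_range) * 1000.0
            direction = _direction_from_pitch(pitch, az)
            start, end, idx = place_free(mt_vox, direction, length_nm)
            paired_with = -1
        mt_vox[idx] = True
        rows.append(dict(id=mid, channel="microtubule", pitch_deg=pitch,
                         length_um=length_nm / 1000.0,
                         paired_with=paired_with,
                         x0_nm=start[0], y0_nm=start[1], z0_nm=start[2],
                         x1_nm=end[0], y1_nm=end[1], z1_nm=end[2]))

    truth = pd.DataFrame(rows)
    return (VolumeMask(actin_vox, spec.voxel_size_nm, "actin"),
            VolumeMask(mt_vox, spec.voxel_size_nm, "microtubule"),
            truth)


# ---------------------------------------------------------------------------
# intensity profiles

def gen_profile(spec: ProfileSpec) -> tuple[LineProfile, dict]:
    """Sample a model curve at equally spaced arclengths, plus truth params."""
    x = np.linspace(0.0, spec.axis_length_um, spec.n_samples)
    y = evaluate_model(spec.model, np.asarray(spec.params, dtype=float), x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    truth = {"model": spec.model, "params": list(spec.params)}
    return LineProfile(x, y), truth
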