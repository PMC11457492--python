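"""Shared fixtures and independent brute-force oracles.

The oracles here recompute neighbour graphs, triplet angles and lattice
enumerations from first principles (all-pairs loops, explicit geometry) so
the package's vectorized implementations are checked against code that
shares nothing with them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tuftmorph import LatticeSpec, PointSet, RenderSpec, gen_lattice_points
from tuftmorph import render_cross_section


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_force_edges(coords: np.ndarray, radius: float) -> list:
    """All-pairs neighbour edges (i, j, d) with i < j, 0 < d <= radius."""
    out = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[j][0] - coords[i][0]
            dy = coords[j][1] - coords[i][1]
            d = math.sqrt(dx * dx + dy * dy)
            if 0 < d <= radius:
                out.append((i, j, d))
    return out


def brute_force_triplet_angles(coords: np.ndarray, edges: list) -> list:
    """Azimuth-consecutive neighbour-pair angles, recomputed independently."""
    adj: dict[int, list[int]] = {}
    for i, j, _ in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    angles = []
    for focal, nbrs in sorted(adj.items()):
        if len(nbrs) < 2:
            continue
        vecs = [(coords[j][0] - coords[focal][0],
                 coords[j][1] - coords[focal][1]) for j in nbrs]
        vecs.sort(key=lambda v: math.atan2(v[1], v[0]))
        k = len(vecs)
        pairs = k if k >= 3 else 1
        for a in range(pairs):
            v1, v2 = vecs[a], vecs[(a + 1) % k]
            dot = v1[0] * v2[0] + v1[1] * v2[1]
            n1 = math.hypot(*v1)
            n2 = math.hypot(*v2)
            ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))
            angles.append(ang if ang > 0 else 180.0)
    return angles


def enumerate_hex_disc(d: float, radius: float) -> np.ndarray:
    """Independent triangular-lattice enumeration inside a disc."""
    pts = []
    row = d * math.sqrt(3) / 2
    jmax = int(radius / row) + 2
    imax = int(radius / d) + 2
    for j in range(-jmax, jmax + 1):
        for i in range(-imax, imax + 1):
            x = i * d + (d / 2 if j % 2 else 0.0)
            y = j * row
            if x * x + y * y <= radius * radius + 1e-9:
                pts.append((x, y))
    return np.array(pts)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rosette() -> PointSet:
    """Centre plus 6-ring at 9 nm: the canonical hexagonal unit."""
    pts, _ = gen_lattice_points(
        LatticeSpec("hex", spacing_nm=9.0, bundle_radius_nm=10.0))
    assert len(pts) == 7
    return pts


@pytest.fixture
def hex_bundle_image():
    """Rendered ~120-filament hexagonal bundle with mild noise."""
    spec = LatticeSpec("hex", spacing_nm=9.0, bundle_radius_nm=53.0,
                       center_nm=(128.0, 128.0), seed=0)
    points, _ = gen_lattice_points(spec)
    image = render_cross_section(
        points, RenderSpec(pixel_size_nm=1.0, psf_sigma_nm=2.0,
                           noise_sd=0.02, image_shape_px=(256, 256), seed=1))
    return points, image


def make_bundle_image(kind: str = "hex", seed: int = 0, jitter_nm: float = 0.0,
                      d: float = 9.0, vacancy: float = 0.0,
                      n_points: int = 121, noise_sd: float = 0.02):
    """Helper used across Fourier and packing tests."""
    spec = LatticeSpec(kind, spacing_nm=d, jitter_sd_nm=jitter_nm,
                       vacancy_fraction=vacancy, bundle_radius_nm=53.0,
                       n_points=n_points if kind == "csr" else None,
                       center_nm=(128.0, 128.0), seed=seed)
    points, _ = gen_lattice_points(spec)
    image = render_cross_section(
        points, RenderSpec(pixel_size_nm=1.0, psf_sigma_nm=2.0,
                           noise_sd=noise_sd, image_shape_px=(256, 256),
                           seed=seed + 1000))
    return points, image
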