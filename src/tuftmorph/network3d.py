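"""3D polymer-network morphometry from two-channel binary volumes.

Consumes segmented masks (actin bundles, microtubules) and quantifies:

* per-polymer centreline traces, calibrated lengths, and pitch relative to
  the apicobasal (z) axis, with 90 deg = vertical;
* actin-microtubule interaction: actin skeleton voxels lying within the
  morphological dilation reach of the microtubule channel, grouped into
  contiguous segments whose calibrated lengths and summed fraction of total
  actin length quantify co-alignment;
* bundle-occupied area versus cell area at chosen depths beneath the apical
  surface, with least-squares slopes;
* apical footprint area and circularity from a 2D boundary mask.

Segmentation itself (e.g. trainable pixel classification of light
micrographs) is out of scope; this module starts from masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.morphology import skeletonize

from .core import VolumeMask

__all__ = [
    "PolymerTrace", "InteractionResult", "DepthAreaResult", "ApicalShape",
    "trace_polymers", "pitch_of", "interaction_map",
    "interaction_volume_fraction", "area_vs_depth", "apical_shape",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PolymerTrace:
    """One polymer's 1-voxel-wide centreline path."""

    id: int
    path_vox: np.ndarray              # (n, 3) as (z, y, x)
    length_um: float
    pitch_deg: float                  # principal-axis pitch
    pitch_end_to_end_deg: float       # end-to-end pitch, for comparison


@dataclass
class InteractionResult:
    dilation_radius_vox: int
    segment_lengths_um: list
    total_interacting_actin_um: float
    total_actin_um: float
    percent_interacting: float


@dataclass
class DepthAreaResult:
    depths_um: list
    bundle_area_um2: list
    cell_area_um2: list
    slope_bundle: float               # um^2 per um depth
    slope_cell: float


@dataclass
class ApicalShape:
    area_um2: float
    circularity: float                # 4*pi*A / P^2


# ---------------------------------------------------------------------------
# tracing and pitch

def pitch_of(path_points: np.ndarray, voxel_size_nm=None) -> float:
    """Pitch (deg) of a path from its principal axis; 90 = vertical.

    ``path_points`` is (n, 3) in (z, y, x) voxel indices (calibrated with
    ``voxel_size_nm`` = (x, y, z)) or, if ``voxel_size_nm`` is None, already
    in physical units. The dominant eigenvector v of the point covariance
    gives pitch = degrees(arcsin(|v_z| / ||v||)).
    """
    pts = np.asarray(path_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 path points")
    if voxel_size_nm is not None:
        sx, sy, sz = voxel_size_nm
        pts = pts * np.array([sz, sy, sx])
    centred = pts - pts.mean(axis=0)
    if not centred.any():
        raise ValueError("all path points identical")
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]         # (z, y, x) components
    return float(np.degrees(np.arcsin(abs(axis[0]) / np.linalg.norm(axis))))


def _end_to_end_pitch(path: np.ndarray, step_zyx: np.ndarray) -> float:
    vec = (path[-1] - path[0]).astype(float) * step_zyx
    n = np.linalg.norm(vec)
    if n == 0:
        return float("nan")
    return float(np.degrees(np.arcsin(abs(vec[0]) / n)))


def _path_length_um(path: np.ndarray, step_zyx: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(path, axis=0) * step_zyx
    return float(np.linalg.norm(steps, axis=1).sum() / 1000.0)


def _longest_skeleton_path(skel: np.ndarray, step_zyx: np.ndarray
                           ) -> np.ndarray:
    """Longest geodesic path through a skeleton (double-sweep heuristic)."""
    vox = np.argwhere(skel)
    if len(vox) == 1:
        return vox
    index = {tuple(v): i for i, v in enumerate(vox)}
    g = nx.Graph()
    g.add_nodes_from(range(len(vox)))
    offsets = [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
    for i, v in enumerate(vox):
        for o in offsets:
            nb = (v[0] + o[0] - 1, v[1] + o[1] - 1, v[2] + o[2] - 1)
            j = index.get(nb)
            if j is not None and j > i:
                w = float(np.linalg.norm((np.array(o) - 1) * step_zyx))
                g.add_edge(i, j, weight=w)
    # farthest node from an arbitrary start, then farthest from that
    start = 0
    for _ in range(2):
        dist = nx.single_source_dijkstra_path_length(g, start)
        start = max(dist, key=dist.get)
    far = start
    dist, paths = nx.single_source_dijkstra(g, far)
    other = max(dist, key=dist.get)
    return vox[paths[other]]


def trace_polymers(mask: VolumeMask, min_length_um: float = 0.5
                   ) -> list[PolymerTrace]:
    """Trace each 26-connected component's longest centreline path.

    Components are skeletonized to 1-voxel-wide centrelines; the longest
    geodesic through each skeleton becomes the trace. Traces shorter than
    ``min_length_um`` are discarded. An empty mask yields an empty list.
    """
    step = mask.step_nm_zyx()
    labels, n = ndimage.label(mask.voxels, structure=_STRUCT26)
    if n == 0:
        return []
    traces = []
    tid = 0
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        skel = skeletonize(comp) if comp.sum() > 2 else comp
        if not skel.any():
            skel = comp
        path = _longest_skeleton_path(skel, step)
        path = path + np.array([s.start for s in sl])
        length = _path_length_um(path, step)
        if length < min_length_um:
            continue
        if len(path) < 2:
            continue
        traces.append(PolymerTrace(
            id=tid, path_vox=path, length_um=length,
            pitch_deg=pitch_of(path, mask.voxel_size_nm),
            pitch_end_to_end_deg=_end_to_end_pitch(path, step)))
        tid += 1
    return traces


# ---------------------------------------------------------------------------
# interaction mapping

def _check_geometry(a: VolumeMask, b: VolumeMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.voxel_size_nm != b.voxel_size_nm:
        raise ValueError("calibration mismatch between channels")


def interaction_map(actin: VolumeMask, mt: VolumeMask,
                    dilation_radius_vox: int = 4,
                    min_length_um: float = 0.5,
                    merge_gap_vox: int = 2) -> InteractionResult:
    """Actin-microtubule interaction lengths via dilation overlap.

    The dilation is ``dilation_radius_vox`` iterations of a unit-radius
    (6-connected) ball. An actin skeleton voxel interacts when it falls
    inside the dilated microtubule channel — equivalent to dilating actin by
    the same element and intersecting with microtubules, but measured along
    actin so the denominator of ``percent_interacting`` is total actin
    length. Contiguous interacting runs along each trace form segments; runs
    separated by <= ``merge_gap_vox`` skeleton voxels are merged (bridging
    single-voxel dropouts).
    """
    _check_geometry(actin, mt)
    if dilation_radius_vox < 1:
        raise ValueError("dilation_radius_vox must be a positive integer")
    step = actin.step_nm_zyx()
    traces = trace_polymers(actin, min_length_um=min_length_um)
    total_actin = sum(t.length_um for t in traces)
    struct = ndimage.generate_binary_structure(3, 1)
    mt_dil = ndimage.binary_dilation(mt.voxels, structure=struct,
                                     iterations=dilation_radius_vox)
    seg_lengths: list[float] = []
    total_interacting = 0.0
    for t in traces:
        p = t.path_vox
        hit = mt_dil[p[:, 0], p[:, 1], p[:, 2]]
        if not hit.any():
            continue
        # merge runs separated by short gaps
        hit = hit.copy()
        on = np.flatnonzero(hit)
        gaps = np.diff(on)
        for a, g in zip(on[:-1], gaps):
            if 1 < g <= merge_gap_vox + 1:
                hit[a:a + g + 1] = True
        # contiguous runs
        padded = np.concatenate([[False], hit, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        step_len = np.linalg.norm(np.diff(p, axis=0) * step, axis=1) / 1000.0
        for s, e in zip(starts, ends):      # run covers samples [s, e)
            if e - s > 1:
                length = float(step_len[s:e - 1].sum())
            else:                            # single-voxel run: one local step
                length = float(step_len[min(s, len(step_len) - 1)])
            seg_lengths.append(length)
            total_interacting += length
    total_interacting = min(total_interacting, total_actin)
    pct = 100.0 * total_interacting / total_actin if total_actin > 0 else 0.0
    return InteractionResult(
        dilation_radius_vox=dilation_radius_vox,
        segment_lengths_um=seg_lengths,
        total_interacting_actin_um=total_interacting,
        total_actin_um=total_actin,
        percent_interacting=pct,
    )


def interaction_volume_fraction(actin: VolumeMask, mt: VolumeMask,
                                dilation_radius_vox: int = 4) -> float:
    """Overlap volume of dilated-microtubule with actin, as a fraction of
    actin volume (the raw-voxel counterpart of the skeleton measurement)."""
    _check_geometry(actin, mt)
    struct = ndimage.generate_binary_structure(3, 1)
    mt_dil = ndimage.binary_dilation(mt.voxels, structure=struct,
                                     iterations=dilation_radius_vox)
    n_actin = int(actin.voxels.sum())
    if n_actin == 0:
        return 0.0
    return float((actin.voxels & mt_dil).sum() / n_actin)


# ---------------------------------------------------------------------------
# area versus depth, apical shape

def area_vs_depth(cell: VolumeMask, bundle: VolumeMask,
                  depths_um=(0.0, 1.5, 3.0, 4.5)) -> DepthAreaResult:
    """Bundle-occupied vs cell cross-sectional area at depths below apex.

    Depth 0 is the first z-slice containing any cell voxel. Cell area is the
    on-voxel count times pixel area; bundle area is the area of the 2D convex
    hull of bundle voxels in the slice (the area the bundle array occupies),
    falling back to the voxel-count area when the hull is degenerate. Slopes
    are ordinary least squares of area on depth.
    """
    _check_geometry(cell, bundle)
    sx, sy, sz = cell.voxel_size_nm
    px_area_um2 = (sx / 1000.0) * (sy / 1000.0)
    z_any = np.flatnonzero(cell.voxels.any(axis=(1, 2)))
    if z_any.size == 0:
        raise ValueError("empty cell mask")
    z0 = int(z_any[0])
    nz = cell.shape[0]
    cell_areas, bundle_areas = [], []
    for depth in depths_um:
        zi = z0 + int(round(depth * 1000.0 / sz))
        if not 0 <= zi < nz:
            raise ValueError(f"depth {depth} um falls outside the volume")
        cell_areas.append(float(cell.voxels[zi].sum()) * px_area_um2)
        pts = np.argwhere(bundle.voxels[zi])  # (y, x) indices
        if len(pts) >= 3:
            pts_um = pts[:, ::-1] * np.array([sx, sy]) / 1000.0
            try:
                hull_area = float(ConvexHull(pts_um).volume)
            except QhullError:      # collinear points
                hull_area = float(len(pts)) * px_area_um2
            bundle_areas.append(max(hull_area, float(len(pts)) * px_area_um2))
        else:
            bundle_areas.append(float(len(pts)) * px_area_um2)
    depths = np.asarray(depths_um, dtype=float)

    def ols_slope(areas) -> float:
        # centred form: exactly zero for constant areas
        if len(depths) < 2:
            return float("nan")
        dd = depths - depths.mean()
        aa = np.asarray(areas) - np.mean(areas)
        return float(np.sum(dd * aa) / np.sum(dd * dd))

    slope_cell = ols_slope(cell_areas)
    slope_bundle = ols_slope(bundle_areas)
    return DepthAreaResult(list(depths), bundle_areas, cell_areas,
                           slope_bundle, slope_cell)


def apical_shape(boundary: np.ndarray, pixel_size_nm: float,
                 contour_smoothing: int = 2) -> ApicalShape:
    """Area and circularity (4*pi*A/P^2) of a single connected 2D region.

    Area comes from the pixel count; the perimeter from the marching-squares
    contour smoothed with a circular moving average of half-width
    ``contour_smoothing`` points. The raw staircase contour overestimates the
    perimeter of smooth shapes by a resolution-independent factor; the
    smoothed contour converges, so a rasterized disc approaches circularity 1
    with resolution.
    """
    mask = np.asarray(boundary).astype(bool)
    if mask.ndim != 2:
        raise ValueError("boundary mask must be 2D")
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty boundary mask")
    if n > 1:
        raise ValueError(f"boundary mask has {n} connected components; "
                         "expected exactly 1")
    px_um = pixel_size_nm / 1000.0
    area = float(mask.sum()) * px_um ** 2
    padded = np.pad(mask.astype(float), 1)
    contour = max(measure.find_contours(padded, 0.5), key=len)
    k = contour_smoothing
    if k > 0 and len(contour) > 2 * k + 1:
        # closed contour: wrap around before averaging
        kern = np.ones(2 * k + 1) / (2 * k + 1)
        contour = np.stack(
            [np.convolve(np.r_[contour[-k:, d], contour[:, d],
                               contour[:k, d]], kern, mode="valid")
             for d in (0, 1)], axis=1)
    perim_px = np.linalg.norm(np.diff(contour, axis=0), axis=1).sum()
    perimeter = float(perim_px) * px_um
    circ = float(4.0 * np.pi * area / perimeter ** 2)
    return ApicalShape(area_um2=area, circularity=circ)
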