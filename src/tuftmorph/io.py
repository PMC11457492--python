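"""File I/O: TIFF images/volumes with JSON calibration sidecars, CSV tables.

Calibration travels in a ``<name>.json`` sidecar next to each TIFF
(``{"pixel_size_nm": ...}`` for planes, ``{"voxel_size_nm": [x, y, z],
"channel": ...}`` for stacks), so the TIFFs stay plain and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImagePlane, LineProfile, PointSet, VolumeMask

__all__ = [
    "write_image", "read_image", "write_volume", "read_volume",
    "write_points", "read_points", "write_profiles", "read_profiles",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: ImagePlane) -> list[Path]:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    side = _sidecar(path)
    side.write_text(json.dumps({"pixel_size_nm": image.pixel_size_nm}))
    return [path, side]


def read_image(path) -> ImagePlane:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pixels = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return ImagePlane(np.asarray(pixels, dtype=float),
                      float(meta["pixel_size_nm"]))


def write_volume(path, volume: VolumeMask) -> list[Path]:
    path = Path(path)
    tifffile.imwrite(path, volume.voxels.astype(np.uint8))
    side = _sidecar(path)
    side.write_text(json.dumps({"voxel_size_nm": list(volume.voxel_size_nm),
                                "channel": volume.channel}))
    return [path, side]


def read_volume(path) -> VolumeMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    vox = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return VolumeMask(np.asarray(vox) > 0,
                      tuple(meta["voxel_size_nm"]),
                      meta.get("channel", "actin"))


def write_points(path, points: PointSet) -> Path:
    path = Path(path)
    df = pd.DataFrame({"id": points.ids,
                       "x_nm": points.coords_nm[:, 0],
                       "y_nm": points.coords_nm[:, 1]})
    df.to_csv(path, index=False)
    return path


def read_points(path, pixel_size_nm: float | None = None) -> PointSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    return PointSet(df["id"].to_numpy(),
                    df[["x_nm", "y_nm"]].to_numpy(dtype=float),
                    pixel_size_nm)


def write_profiles(path, profiles: list[LineProfile]) -> Path:
    path = Path(path)
    frames = []
    for i, p in enumerate(profiles):
        frames.append(pd.DataFrame({"profile_id": i,
                                    "arclength_um": p.arclength_um,
                                    "intensity": p.intensity}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_profiles(path) -> list[LineProfile]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("profile_id", sort=True):
        out.append(LineProfile(grp["arclength_um"].to_numpy(dtype=float),
                               grp["intensity"].to_numpy(dtype=float)))
    return out
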