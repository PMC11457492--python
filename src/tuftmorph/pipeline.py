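"""End-to-end orchestration: simulate -> analyze -> report.

A single YAML/JSON config drives a full run so a published analysis is
re-runnable from one file. Every source of randomness derives from the one
global seed: stage i draws its seed from
``numpy.random.SeedSequence([global_seed, i]))`` (reduced mod 2^31), so any
stage is independently reproducible. Outputs are CSV/JSON/TIFF only;
``report.json`` contains no timestamps, making repeat runs byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as tio
from . import lattice_fourier as lf
from .core import ImagePlane
from . import linescan as ls
from . import network3d as n3
from . import packing as pk
from . import synthetic as syn

__all__ = ["ConfigError", "load_config", "validate_config", "run_pipeline",
           "summarize"]

logger = logging.getLogger("tuftmorph")


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


_LATTICE_KEYS = {"lattice_kind", "spacing_nm", "jitter_sd_nm",
                 "vacancy_fraction", "bundle_radius_nm", "n_points",
                 "center_nm", "seed"}
_RENDER_KEYS = {"pixel_size_nm", "psf_sigma_nm", "noise_sd", "polarity",
                "image_shape_px", "background_level", "blob_amplitude",
                "seed"}
_NETWORK_KEYS = {"volume_shape_vox", "voxel_size_nm", "n_actin", "n_mt",
                 "pitch_mean_deg", "pitch_sd_deg", "length_um_range",
                 "paired_fraction", "pair_offset_nm", "seed", "max_retries"}
_PROFILE_KEYS = {"model", "params", "axis_length_um", "n_samples",
                 "noise_sd", "n_profiles", "seed"}

_STAGE_SCHEMAS = {
    "simulate": {"stage", "lattice", "render", "network", "profiles"},
    "packing": {"stage", "points", "image", "radius_nm",
                "expected_spacing_nm"},
    "fft": {"stage", "image", "mode", "spacing_range_nm", "points",
            "accept_factor"},
    "network": {"stage", "actin", "mt", "dilation_radius_vox",
                "min_length_um"},
    "linescan": {"stage", "profiles", "model", "normalize"},
}
_STAGE_ORDER = {"simulate": 0, "packing": 1, "fft": 1, "network": 1,
                "linescan": 1}
_TOP_KEYS = {"seed", "outdir", "stages"}


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return yaml.safe_load(path.read_text())


def validate_config(config: dict) -> None:
    """Reject unknown keys and malformed stage blocks before any work."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "stages" not in config or not isinstance(config["stages"], list) \
            or not config["stages"]:
        raise ConfigError("config needs a non-empty 'stages' list")
    for block in config["stages"]:
        if not isinstance(block, dict) or "stage" not in block:
            raise ConfigError("each stage block needs a 'stage' name")
        name = block["stage"]
        if name not in _STAGE_SCHEMAS:
            raise ConfigError(f"unknown stage '{name}'")
        unknown = set(block) - _STAGE_SCHEMAS[name]
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in stage '{name}'")
        if name == "simulate":
            for sub, allowed in (("lattice", _LATTICE_KEYS),
                                 ("render", _RENDER_KEYS),
                                 ("network", _NETWORK_KEYS),
                                 ("profiles", _PROFILE_KEYS)):
                extra = set(block.get(sub, {})) - allowed
                if extra:
                    raise ConfigError(f"unknown key(s) {sorted(extra)} in "
                                      f"simulate.{sub}")


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form of the config."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def stage_seed(global_seed: int, stage_index: int) -> int:
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def summarize(values, bin_width: float | None = None) -> dict:
    """Descriptive statistics: n, median (midpoint convention), IQR, range,
    and a histogram with configurable bin width."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    q1, q3 = np.percentile(v, [25, 75])
    if bin_width is not None:
        lo = np.floor(v.min() / bin_width) * bin_width
        nb = max(1, int(np.ceil((v.max() - lo) / bin_width)))
        edges = lo + bin_width * np.arange(nb + 1)
    else:
        edges = 10
    counts, edges = np.histogram(v, bins=edges)
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "iqr": float(q3 - q1),
        "min": float(v.min()),
        "max": float(v.max()),
        "histogram": {"edges": [float(e) for e in edges],
                      "counts": [int(c) for c in counts]},
    }


# ---------------------------------------------------------------------------
# stage runners

def _run_simulate(block: dict, outdir: Path, seed: int) -> tuple[list, dict]:
    outputs: list[Path] = []
    summary: dict = {}
    if "lattice" in block:
        lat_kwargs = dict(block["lattice"])
        lat_kwargs.setdefault("seed", seed)
        if "center_nm" in lat_kwargs:
            lat_kwargs["center_nm"] = tuple(lat_kwargs["center_nm"])
        render_kwargs = dict(block.get("render", {}))
        render_kwargs.setdefault("seed", seed + 1)
        if "image_shape_px" in render_kwargs:
            render_kwargs["image_shape_px"] = tuple(
                render_kwargs["image_shape_px"])
        render = syn.RenderSpec(**render_kwargs)
        if "center_nm" not in lat_kwargs:
            h, w = render.image_shape_px
            lat_kwargs["center_nm"] = (w * render.pixel_size_nm / 2.0,
                                       h * render.pixel_size_nm / 2.0)
        spec = syn.LatticeSpec(**lat_kwargs)
        points, truth = syn.gen_lattice_points(spec)
        outputs.append(tio.write_points(outdir / "points_truth.csv", points))
        image = syn.render_cross_section(points, render)
        outputs.extend(tio.write_image(outdir / "cross_section.tif", image))
        summary["lattice"] = {"n_points": len(points)}
    if "network" in block:
        net_kwargs = dict(block["network"])
        net_kwargs.setdefault("seed", seed + 2)
        for key in ("volume_shape_vox", "voxel_size_nm", "length_um_range"):
            if key in net_kwargs:
                net_kwargs[key] = tuple(net_kwargs[key])
        actin, mt, truth = syn.gen_network_volume(
            syn.Network3DSpec(**net_kwargs))
        outputs.extend(tio.write_volume(outdir / "actin.tif", actin))
        outputs.extend(tio.write_volume(outdir / "microtubule.tif", mt))
        truth.to_csv(outdir / "network_truth.csv", index=False)
        outputs.append(outdir / "network_truth.csv")
        summary["network"] = {
            "n_polymers": len(truth),
            "median_pitch_deg": float(truth["pitch_deg"].median()),
        }
    if "profiles" in block:
        pr = dict(block["profiles"])
        n_profiles = int(pr.pop("n_profiles", 1))
        pr.setdefault("seed", seed + 3)
        base_seed = pr["seed"]
        if "params" in pr:
            pr["params"] = tuple(pr["params"])
        profs = []
        for i in range(n_profiles):
            pr["seed"] = base_seed + i
            prof, truth_params = syn.gen_profile(syn.ProfileSpec(**pr))
            profs.append(prof)
        outputs.append(tio.write_profiles(outdir / "profiles.csv", profs))
        (outdir / "profiles_truth.json").write_text(
            json.dumps(truth_params))
        outputs.append(outdir / "profiles_truth.json")
        summary["profiles"] = {"n_profiles": n_profiles}
    if not outputs:
        raise ConfigError("simulate stage produced nothing: give at least "
                          "one of lattice/network/profiles")
    return outputs, summary


def _run_packing(block: dict, outdir: Path, seed: int) -> tuple[list, dict]:
    if "image" in block:
        image = tio.read_image(block["image"])
        points = pk.detect_centers(
            image, float(block.get("expected_spacing_nm", 9.2)))
    else:
        src = block.get("points", outdir / "points_truth.csv")
        points = tio.read_points(src)
    graph = pk.build_neighbor_graph(points,
                                    float(block.get("radius_nm", 12.0)))
    summary = pk.summarize_packing(points, graph)
    outputs = [tio.write_points(outdir / "packing_points.csv", points)]
    import pandas as pd

    pd.DataFrame(graph.edges, columns=["i", "j", "distance_nm"]).to_csv(
        outdir / "packing_edges.csv", index=False)
    outputs.append(outdir / "packing_edges.csv")
    (outdir / "packing_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    outputs.append(outdir / "packing_summary.json")
    return outputs, summary.to_dict()


def _run_fft(block: dict, outdir: Path, seed: int) -> tuple[list, dict]:
    image = tio.read_image(block.get("image", outdir / "cross_section.tif"))
    spacing_range = tuple(block.get("spacing_range_nm", (7.0, 12.0)))
    spec = lf.power_spectrum(image)
    refl = lf.detect_reflections(spec, spacing_range,
                                 accept_factor=float(
                                     block.get("accept_factor", 5.0)))
    mode = block.get("mode", "hexagonal")
    summary: dict = {"n_reflections": len(refl),
                     "ring_radius_nm_inv": refl.ring_radius_nm_inv,
                     "mode": mode}
    outputs = []
    import pandas as pd

    pd.DataFrame({"kx_nm_inv": refl.freqs_nm_inv[:, 0]
                  if len(refl) else [],
                  "ky_nm_inv": refl.freqs_nm_inv[:, 1]
                  if len(refl) else [],
                  "magnitude": refl.magnitudes}).to_csv(
        outdir / "reflections.csv", index=False)
    outputs.append(outdir / "reflections.csv")
    if len(refl):
        result = lf.lattice_filter(image, refl, mode)
        outputs.extend(tio.write_image(outdir / "filtered.tif",
                                       result.filtered_image))
        outputs.extend(tio.write_image(
            outdir / "highlighted_mask.tif",
            ImagePlane(result.highlighted_mask.astype(float),
                       image.pixel_size_nm)))
        pts_src = block.get("points", outdir / "points_truth.csv")
        if Path(pts_src).exists():
            points = tio.read_points(pts_src)
            summary["highlighted_fraction"] = lf.highlighted_fraction(
                result, points)
    else:
        summary["diagnostic"] = refl.diagnostic
    (outdir / "fft_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    outputs.append(outdir / "fft_summary.json")
    return outputs, summary


def _run_network(block: dict, outdir: Path, seed: int) -> tuple[list, dict]:
    actin = tio.read_volume(block.get("actin", outdir / "actin.tif"))
    mt = tio.read_volume(block.get("mt", outdir / "microtubule.tif"))
    min_len = float(block.get("min_length_um", 0.5))
    traces = n3.trace_polymers(actin, min_length_um=min_len)
    mt_traces = n3.trace_polymers(mt, min_length_um=min_len)
    inter = n3.interaction_map(
        actin, mt,
        dilation_radius_vox=int(block.get("dilation_radius_vox", 4)),
        min_length_um=min_len)
    import pandas as pd

    rows = [dict(id=t.id, channel=ch, length_um=t.length_um,
                 pitch_deg=t.pitch_deg,
                 pitch_end_to_end_deg=t.pitch_end_to_end_deg)
            for ch, ts in (("actin", traces), ("microtubule", mt_traces))
            for t in ts]
    pd.DataFrame(rows).to_csv(outdir / "traces.csv", index=False)
    pd.DataFrame({"segment_length_um": inter.segment_lengths_um}).to_csv(
        outdir / "interactions.csv", index=False)
    summary = {
        "n_actin_traces": len(traces),
        "n_mt_traces": len(mt_traces),
        "median_actin_pitch_deg": float(np.median(
            [t.pitch_deg for t in traces])) if traces else float("nan"),
        "median_mt_pitch_deg": float(np.median(
            [t.pitch_deg for t in mt_traces])) if mt_traces else float("nan"),
        "percent_interacting": inter.percent_interacting,
        "total_actin_um": inter.total_actin_um,
        "median_interaction_length_um": float(np.median(
            inter.segment_lengths_um)) if inter.segment_lengths_um
        else float("nan"),
    }
    (outdir / "network_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return ([outdir / "traces.csv", outdir / "interactions.csv",
             outdir / "network_summary.json"], summary)


def _run_linescan(block: dict, outdir: Path, seed: int) -> tuple[list, dict]:
    profiles = tio.read_profiles(block.get("profiles",
                                           outdir / "profiles.csv"))
    model = block.get("model", "lognormal")
    if block.get("normalize", False):
        profiles = [ls.normalize_profile(p) for p in profiles]
    fits = [ls.fit_profile(p, model, seed=seed) for p in profiles]
    import pandas as pd

    rows = []
    for i, f in enumerate(fits):
        rows.append(dict(profile_id=i, model=f.model,
                         rss=f.rss, converged=f.converged,
                         peak_position_um=f.peak_position_um,
                         **{f"p{k}": float(v)
                            for k, v in enumerate(f.params)}))
    pd.DataFrame(rows).to_csv(outdir / "fits.csv", index=False)
    peaks = [f.peak_position_um for f in fits
             if f.peak_position_um is not None]
    summary = {"model": model, "n_profiles": len(profiles),
               "n_converged": int(sum(f.converged for f in fits))}
    if peaks:
        summary["peaks"] = summarize(peaks)
    if len(profiles) >= 2:
        _, pooled, _ = ls.aggregate_profiles(profiles, model, seed=seed)
        summary["pooled"] = {
            "params": [float(v) for v in pooled.params],
            "rss": pooled.rss,
            "peak_position_frac": pooled.peak_position_um,
            "converged": pooled.converged,
        }
    (outdir / "linescan_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return [outdir / "fits.csv", outdir / "linescan_summary.json"], summary


_RUNNERS = {"simulate": _run_simulate, "packing": _run_packing,
            "fft": _run_fft, "network": _run_network,
            "linescan": _run_linescan}


def run_pipeline(config: dict, outdir=None) -> dict:
    """Validate, execute stages in dependency order, and write a report.

    A failed stage aborts the stages after it; the report records partial
    results. Returns the report dict (also written to ``report.json``).
    """
    from . import __version__

    validate_config(config)
    out = Path(outdir if outdir is not None else config.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0))

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    blocks = sorted(enumerate(config["stages"]),
                    key=lambda t: (_STAGE_ORDER[t[1]["stage"]], t[0]))
    report = {"version": __version__, "config_hash": config_hash(config),
              "seed": global_seed, "stages": []}
    failed = False
    try:
        for idx, block in blocks:
            name = block["stage"]
            entry = {"name": name, "status": "skipped", "outputs": []}
            report["stages"].append(entry)
            if failed:
                continue
            seed = stage_seed(global_seed, idx)
            logger.info("stage %s (seed %d)", name, seed)
            try:
                outputs, summary = _RUNNERS[name](block, out, seed)
            except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                entry["status"] = "failed"
                entry["error"] = f"{name}: {exc}"
                logger.info("stage %s failed: %s", name, exc)
                failed = True
                continue
            entry["status"] = "ok"
            # manifest paths are relative to the run directory so repeat
            # runs in different directories stay byte-comparable
            entry["outputs"] = sorted(
                str(Path(p).resolve().relative_to(out.resolve()))
                if Path(p).resolve().is_relative_to(out.resolve())
                else str(Path(p)) for p in outputs)
            entry["summary"] = summary
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
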