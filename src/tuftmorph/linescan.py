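"""Arclength intensity profiles and regionalization model fits.

Linescans are drawn tip-to-base along a bundle axis (apical tip at arclength
0) and averaged over a perpendicular width, then fitted with the models used
to describe protein regionalization along the core bundle: a lognormal bump
(single intracellular peak), a four-parameter sigmoid (plateau-to-plateau
transition), a fourth-order polynomial, or an exponential decay (signal
tapering toward the rootlet). See :mod:`tuftmorph.models` for the exact
parameterizations.

Fitting is nonlinear least squares with documented initialization and a
deterministic 5-start multi-start; the best-RSS candidate wins and a
non-convergent fit returns ``converged=False`` with best-effort parameters
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .core import ImagePlane, LineProfile
from .models import MODEL_ARITY, evaluate_model

__all__ = [
    "LineProfile", "FitResult",
    "extract_profile", "normalize_profile", "fit_profile",
    "aggregate_profiles",
]

_N_STARTS = 5


@dataclass
class FitResult:
    model: str
    params: np.ndarray
    peak_position_um: float | None
    plateaus: tuple[float, float] | None
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return evaluate_model(self.model, self.params, x)


# ---------------------------------------------------------------------------
# extraction

def extract_profile(image: ImagePlane, polyline_nm: np.ndarray,
                    width_px: int = 10) -> LineProfile:
    """Sample intensity along a polyline, averaged across its width.

    Intensity is bilinearly interpolated at unit-pixel arclength steps and
    averaged over ``width_px`` samples placed perpendicular to the local
    direction (1 px apart, centred on the line). Arclength is returned in um.
    """
    poly = np.atleast_2d(np.asarray(polyline_nm, dtype=float))
    if len(poly) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    px = image.pixel_size_nm
    h, w = image.shape
    bad = np.where((poly[:, 0] < 0) | (poly[:, 0] > w * px)
                   | (poly[:, 1] < 0) | (poly[:, 1] > h * px))[0]
    if bad.size:
        raise ValueError(f"polyline exits image bounds at vertices "
                         f"{bad.tolist()}")
    # index coordinates: sample i sits at (i + 0.5) * px
    verts = poly / px - 0.5
    seg = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if seg_len.sum() == 0:
        raise ValueError("polyline has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, cum[-1] + 1e-9, 1.0)
    xs = np.interp(s, cum, verts[:, 0])
    ys = np.interp(s, cum, verts[:, 1])
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm     # unit normal
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    vals = np.empty((width_px, len(s)))
    for k, off in enumerate(offsets):
        rows = ys + off * ny
        cols = xs + off * nx
        vals[k] = map_coordinates(image.pixels, [rows, cols], order=1,
                                  mode="nearest")
    intensity = vals.mean(axis=0)
    return LineProfile(s * px / 1000.0, intensity, width_px=width_px)


def normalize_profile(profile: LineProfile) -> LineProfile:
    """Min-max normalize intensities to [0, 1]."""
    lo, hi = profile.intensity.min(), profile.intensity.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant profile")
    return LineProfile(profile.arclength_um.copy(),
                       (profile.intensity - lo) / (hi - lo),
                       width_px=profile.width_px, normalized=True)


# ---------------------------------------------------------------------------
# fitting

def _init_params(model: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if model == "lognormal":
        mode = x[np.argmax(y)]
        if mode <= 0:
            mode = x[x > 0][0] if (x > 0).any() else 1.0
        return np.array([max(y.max(), 1e-9), mode, 0.5])
    if model == "four_pl":
        k = max(1, len(x) // 10)
        bottom = float(y[:k].mean())
        top = float(y[-k:].mean())
        half = 0.5 * (bottom + top)
        crossings = np.where(np.diff(np.sign(y - half)))[0]
        mid = float(x[crossings[0]]) if crossings.size else float(np.median(x))
        return np.array([bottom, top, mid, 1.0])
    if model == "exp_decay":
        offset = float(y.min())
        amp = max(float(y[0] - offset), 1e-9)
        z = np.clip(y - offset, 1e-12, None)
        pos = z > 1e-9
        if pos.sum() >= 2:
            slope = np.polyfit(x[pos], np.log(z[pos]), 1)[0]
            lam = -1.0 / slope if slope < 0 else (x[-1] - x[0])
        else:
            lam = x[-1] - x[0]
        return np.array([amp, max(lam, 1e-6), offset])
    raise ValueError(model)


def _rss(model: str, params: np.ndarray, x: np.ndarray, y: np.ndarray
         ) -> float:
    r = evaluate_model(model, params, x) - y
    return float(r @ r)


def _quartic_peak(params: np.ndarray, lo: float, hi: float) -> float:
    deriv = np.polynomial.polynomial.polyder(params)
    roots = np.polynomial.polynomial.polyroots(deriv)
    cands = [lo, hi] + [float(r.real) for r in roots
                        if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
    vals = evaluate_model("quartic", params, np.asarray(cands))
    return float(cands[int(np.argmax(vals))])


def fit_profile(profile: LineProfile, model: str, seed: int = 0) -> FitResult:
    """Fit a named model to a profile by multi-start least squares.

    Initialization: lognormal from the argmax (mode), shape 0.5, amplitude
    from the max; 4PL plateaus from the first/last deciles with the midpoint
    at the half-range crossing; exp_decay from a log-linear fit; quartic in
    closed form (linear least squares, always converged). Five jittered
    starts from a fixed RNG; the lowest-RSS candidate is kept.
    """
    if model not in MODEL_ARITY or model == "constant":
        raise ValueError(f"cannot fit model {model!r}")
    x = profile.arclength_um
    y = profile.intensity
    if len(x) < MODEL_ARITY[model] + 3:
        raise ValueError("too few samples for this model")

    if model == "quartic":
        params = np.polynomial.polynomial.polyfit(x, y, 4)
        rss = _rss(model, params, x, y)
        return FitResult(model, params,
                         _quartic_peak(params, float(x[0]), float(x[-1])),
                         None, rss, True)

    x0 = _init_params(model, x, y)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(_N_STARTS - 1):
        starts.append(x0 * (1.0 + 0.15 * rng.standard_normal(len(x0))))

    def residual(p):
        return evaluate_model(model, p, x) - y

    best_params, best_rss, best_ok = x0, _rss(model, x0, x, y), False
    for p0 in starts:
        if model == "lognormal":
            p0 = np.array([p0[0], max(abs(p0[1]), 1e-6),
                           max(abs(p0[2]), 1e-6)])
        try:
            sol = least_squares(residual, p0, x_scale="jac",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=2000)
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if np.all(np.isfinite(sol.x)) and rss < best_rss - 1e-15 or (
                not best_ok and np.all(np.isfinite(sol.x)) and
                rss <= best_rss + 1e-15):
            best_params, best_rss, best_ok = sol.x, rss, bool(sol.success)

    params = np.asarray(best_params, dtype=float)
    peak = None
    plateaus = None
    if model == "lognormal":
        params = np.array([params[0], abs(params[1]), abs(params[2])])
        peak = float(np.clip(params[1], x[0], x[-1]))
    elif model == "four_pl":
        b, t, m, hill = params
        if hill < 0:     # canonicalize: bottom = plateau on the x->0 side
            b, t, hill = t, b, -hill
            params = np.array([b, t, m, hill])
        plateaus = (float(params[0]), float(params[1]))
    return FitResult(model, params, peak, plateaus, best_rss,
                     best_ok and bool(np.all(np.isfinite(params))))


def aggregate_profiles(profiles: list[LineProfile], model: str,
                       n_grid: int = 100, seed: int = 0):
    """Pool profiles on a common fractional-arclength grid and fit once.

    Each profile is resampled to ``n_grid`` points on fractional arclength
    [0, 1]; a single pooled fit through all resampled points mirrors the one
    line drawn through all raw traces, and per-profile fits are returned
    alongside. Returns ``(grid, mean_curve), pooled_fit, per_profile_fits``;
    pooled peak positions are therefore in fractional units.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to aggregate")
    grid = np.linspace(0.0, 1.0, n_grid)
    resampled = []
    for p in profiles:
        if p.length_um <= 0:
            raise ValueError("profile of zero length")
        frac = p.arclength_um / p.length_um
        resampled.append(np.interp(grid, frac, p.intensity))
    resampled = np.asarray(resampled)
    mean_curve = resampled.mean(axis=0)
    pooled_x = np.tile(grid, len(profiles))
    pooled_y = resampled.ravel()
    order = np.argsort(pooled_x, kind="stable")
    pooled_fit = _fit_xy(pooled_x[order], pooled_y[order], model, seed=seed)
    per_profile = [_fit_xy(grid, r, model, seed=seed) for r in resampled]
    return (grid, mean_curve), pooled_fit, per_profile


def _fit_xy(x: np.ndarray, y: np.ndarray, model: str, seed: int = 0
            ) -> FitResult:
    """Fit on bare (x, y) arrays (allows repeated x from pooling)."""

    class _Raw:
        arclength_um = None
        intensity = None

    prof = _Raw()
    prof.arclength_um = np.asarray(x, dtype=float)
    prof.intensity = np.asarray(y, dtype=float)
    return fit_profile(prof, model, seed=seed)  # type: ignore[arg-type]
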