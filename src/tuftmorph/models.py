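"""Parametric intensity-profile models shared by the generator and fitter.

Parameter conventions (x in um along the bundle axis, tip at 0):

* ``lognormal``  (amplitude, mode_um, shape):
  A * exp(-(ln(x/m))^2 / (2 s^2)); value 0 at x <= 0. The analytic peak of
  this parameterization is at x = m.
* ``four_pl``    (bottom, top, midpoint_um, hill_per_um): Boltzmann sigmoid
  bottom + (top - bottom) / (1 + exp(-hill * (x - midpoint))). A logistic in
  arclength is used rather than the log-x Hill form because profiles start at
  x = 0 where x^hill is degenerate; for hill * midpoint >> 1 the value at
  x = 0 is the bottom plateau.
* ``quartic``    (c0..c4): fourth-order polynomial, ascending powers.
* ``exp_decay``  (amplitude, lambda_um, offset): A * exp(-x / lambda) + offset.
* ``constant``   (value,).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MODEL_ARITY", "evaluate_model"]

MODEL_ARITY = {
    "lognormal": 3,
    "four_pl": 4,
    "quartic": 5,
    "exp_decay": 3,
    "constant": 1,
}


def _lognormal(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    amp, mode, shape = p
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    with np.errstate(divide="ignore"):
        out[pos] = amp * np.exp(-(np.log(x[pos] / mode) ** 2)
                                / (2.0 * shape ** 2))
    return out


def _four_pl(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    bottom, top, mid, hill = p
    z = np.clip(-hill * (x - mid), -700, 700)
    return bottom + (top - bottom) / (1.0 + np.exp(z))


def _quartic(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(x, p)


def _exp_decay(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    amp, lam, offset = p
    return amp * np.exp(-x / lam) + offset


_FUNCS = {
    "lognormal": _lognormal,
    "four_pl": _four_pl,
    "quartic": _quartic,
    "exp_decay": _exp_decay,
    "constant": lambda p, x: np.full_like(np.asarray(x, float), p[0]),
}


def evaluate_model(model: str, params, x) -> np.ndarray:
    """Evaluate a named model at arclengths ``x`` (um)."""
    if model not in _FUNCS:
        raise ValueError(f"unknown model {model!r}")
    params = np.asarray(params, dtype=float)
    if len(params) != MODEL_ARITY[model]:
        raise ValueError(f"{model} takes {MODEL_ARITY[model]} params")
    return _FUNCS[model](params, np.asarray(x, dtype=float))
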