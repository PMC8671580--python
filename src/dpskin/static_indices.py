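"""Conventional planar indices and the regressions linking them to the
kinetic indices.

The early and delayed heart-to-mediastinum ratios (eHMR, dHMR) are
duration-weighted window means of the heart curve divided by those of the
mediastinal curve (windows 10-15 min and 190-195 min).  The washout rate is

    WR = [(He - Me) - (Hd - Md)] / (He - Me)

with all four terms decay-corrected to a common reference time (the reference
time cancels in the ratio, so curves corrected to injection time are used
directly).

Regression helpers reproduce the model families used to relate new and
existing indices: ordinary least squares for the linear relations, and the
one-phase-association ("monomolecular growth") model
``y = Y0 + (plateau - Y0) * (1 - exp(-rate * x))`` for the iLoss-WR relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .tac import I123_HALF_LIFE_MIN, TimeActivityCurve, decay_correct

EARLY_WINDOW_MIN = (10.0, 15.0)
DELAYED_WINDOW_MIN = (190.0, 195.0)


def _window_mean(tac: TimeActivityCurve, window: tuple[float, float]) -> float:
    mask = tac.schedule.window_mask(*window)
    if not mask.any():
        raise ValueError(f"no frames inside window {window} min")
    w = tac.schedule.duration_min[mask]
    return float(np.sum(w * tac.values[mask]) / np.sum(w))


def hmr(
    htac: TimeActivityCurve,
    mtac: TimeActivityCurve,
    window: tuple[float, float] = EARLY_WINDOW_MIN,
) -> float:
    """Heart-to-mediastinum ratio over a time window (duration-weighted)."""
    h = _window_mean(htac, window)
    m = _window_mean(mtac, window)
    if m <= 0:
        raise ValueError("mediastinal window mean must be positive")
    return h / m


def washout_rate(
    htac: TimeActivityCurve,
    mtac: TimeActivityCurve,
    early_window: tuple[float, float] = EARLY_WINDOW_MIN,
    delayed_window: tuple[float, float] = DELAYED_WINDOW_MIN,
    half_life_min: float = I123_HALF_LIFE_MIN,
) -> float:
    """Washout rate of the mediastinum-subtracted, decay-corrected heart curve.

    Returns NaN (undefined) when the early mediastinum-subtracted uptake
    ``He - Me`` is non-positive.  WR may be negative when uptake increases.
    """
    if htac.decay_corrected != mtac.decay_corrected:
        raise ValueError("heart and mediastinal curves disagree on decay correction")
    if not htac.decay_corrected:
        htac = decay_correct(htac, half_life_min)
        mtac = decay_correct(mtac, half_life_min)
    he = _window_mean(htac, early_window)
    me = _window_mean(mtac, early_window)
    hd = _window_mean(htac, delayed_window)
    md = _window_mean(mtac, delayed_window)
    early = he - me
    if early <= 0:
        return float("nan")
    return (early - (hd - md)) / early


@dataclass
class RegressionModel:
    """A fitted linear or monomolecular-growth regression."""

    kind: str  # "linear" or "monomolecular"
    params: dict[str, float]
    r_squared: float
    n: int
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            out = self.params["slope"] * x + self.params["intercept"]
        else:
            y0, plateau, rate = (
                self.params["y0"], self.params["plateau"], self.params["rate"],
            )
            out = y0 + (plateau - y0) * (1.0 - np.exp(-rate * x))
        return out if out.shape else float(out)


def fit_linear(x, y) -> RegressionModel:
    """Ordinary least-squares line through (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    return RegressionModel(
        kind="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def _mono(x, y0, plateau, rate):
    return y0 + (plateau - y0) * (1.0 - np.exp(-rate * x))


def fit_monomolecular(x, y, rate_starts=None) -> RegressionModel:
    """Least-squares one-phase-association fit, multi-start over the rate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if rate_starts is None:
        span = max(np.ptp(x), 1e-12)
        rate_starts = np.geomspace(0.1 / span, 100.0 / span, 8)
    best = None
    converged = False
    for r0 in rate_starts:
        try:
            popt, _ = curve_fit(
                _mono, x, y, p0=[y.min(), y.max(), r0], maxfev=10000,
                xtol=1e-13, ftol=1e-13,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _mono(x, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
            converged = True
    if best is None:
        return RegressionModel(
            "monomolecular", {"y0": np.nan, "plateau": np.nan, "rate": np.nan},
            r_squared=np.nan, n=int(x.size), converged=False,
        )
    ssr, popt = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return RegressionModel(
        "monomolecular",
        {"y0": float(popt[0]), "plateau": float(popt[1]), "rate": float(popt[2])},
        r_squared=r2,
        n=int(x.size),
        converged=converged,
    )
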