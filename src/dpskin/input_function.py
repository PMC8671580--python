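"""Plasma input functions from mediastinal time-activity curves.

The mediastinal curve (mTAC) is a surrogate for whole-blood activity.  It is
fitted with a three-phase exponential (with a peak-time offset and a constant
term) and converted to a plasma parent-tracer input function (PIF) with two
population-based corrections:

* **BPR** — blood-to-plasma activity ratio, floored at 0.6 (haematocrit 40%)
  for the first 45 s and rising smoothly toward a plateau;
* **PBMC** — parent fraction in plasma, starting at 1 and declining
  exponentially toward a ~30% plateau.

``PIF(t) = mTAC_fit(t) * PBMC(t) / BPR(t)``.  The tissue curve is the heart
curve minus the *fitted* mediastinal curve.

The BPR/PBMC shapes are parametric stand-ins for population curves that were
originally derived from blood sampling; their time constants are package
defaults, fully configurable, and documented as assumptions in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .tac import FrameSchedule, TimeActivityCurve


@dataclass
class TriExpFit:
    """Three-phase exponential fit of a mediastinal curve.

    For ``t >= t0`` the model is ``sum_i A_i * exp(-rate_i * (t - t0)) + C``;
    for ``t < t0`` (pre-peak extrapolation, used only when subtracting the
    fitted curve from heart frames acquired before the bolus peak) the value
    is held at the peak value ``sum(A) + C``.
    """

    t0_min: float
    amplitudes: np.ndarray  # cps/pixel, length 3, >= 0
    rates_per_min: np.ndarray  # 1/min, length 3, sorted descending, >= 0
    constant: float  # cps/pixel, >= 0
    fit_window_min: tuple[float, float] = (0.0, 30.0)
    wssr: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        rates = np.asarray(self.rates_per_min, dtype=float)
        if amps.shape != rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(amps < 0) or np.any(rates < 0) or self.constant < 0:
            raise ValueError("amplitudes, rates and constant must be non-negative")
        order = np.argsort(rates)[::-1]
        self.amplitudes = amps[order]
        self.rates_per_min = rates[order]

    def __call__(self, t_min) -> np.ndarray:
        t = np.maximum(np.asarray(t_min, dtype=float), self.t0_min)
        dt = t - self.t0_min
        out = self.constant + np.sum(
            self.amplitudes[:, None] * np.exp(-np.outer(self.rates_per_min, dt)),
            axis=0,
        )
        return out if out.shape else float(out)


@dataclass
class CorrectionCurves:
    """Population-based blood-to-plasma ratio and parent-fraction curves.

    All times in minutes.  ``bpr`` is continuous, equal to ``bpr_floor`` up to
    ``bpr_floor_end_min`` and monotonically non-decreasing toward
    ``bpr_plateau``.  ``pbmc`` starts at 1 and decays toward ``pbmc_plateau``.
    """

    bpr_floor: float = 0.6
    bpr_floor_end_min: float = 45.0 / 60.0
    bpr_plateau: float = 1.0
    bpr_rate_per_min: float = 0.05
    pbmc_plateau: float = 0.30
    pbmc_rate_per_min: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 < self.pbmc_plateau < 1.0):
            raise ValueError("pbmc_plateau must lie in (0, 1)")
        if self.bpr_floor <= 0:
            raise ValueError("bpr_floor must be positive")
        if self.bpr_plateau < self.bpr_floor:
            raise ValueError("bpr_plateau must be >= bpr_floor")
        if self.bpr_rate_per_min < 0 or self.pbmc_rate_per_min < 0:
            raise ValueError("rates must be non-negative")

    def bpr(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        rise = self.bpr_floor + (self.bpr_plateau - self.bpr_floor) * (
            1.0 - np.exp(-self.bpr_rate_per_min * np.maximum(t - self.bpr_floor_end_min, 0.0))
        )
        out = np.where(t <= self.bpr_floor_end_min, self.bpr_floor, rise)
        return out if out.shape else float(out)

    def pbmc(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        out = self.pbmc_plateau + (1.0 - self.pbmc_plateau) * np.exp(
            -self.pbmc_rate_per_min * t
        )
        return out if out.shape else float(out)


def make_corrections(**params) -> CorrectionCurves:
    """Build :class:`CorrectionCurves`, validating parameter ranges."""
    return CorrectionCurves(**params)


class ParametricPIF:
    """Plasma input function ``mfit(t) * pbmc(t) / bpr(t)`` as a callable of
    minutes; this is the parametric curve used for convolution on fine grids
    (measured curves are never interpolated across scan gaps)."""

    def __init__(self, mfit: TriExpFit, corrections: CorrectionCurves):
        self.mfit = mfit
        self.corrections = corrections

    def __call__(self, t_min) -> np.ndarray:
        bpr = self.corrections.bpr(t_min)
        if np.any(np.asarray(bpr) <= 0):
            raise ValueError("blood-to-plasma ratio must be positive")
        return self.mfit(t_min) * self.corrections.pbmc(t_min) / bpr


_BASE_RATES = np.array([1.0, 0.1, 0.01])  # 1/min; fast bolus, washout, slow phases


def _design_matrix(t_min: np.ndarray, rates: np.ndarray, t0: float) -> np.ndarray:
    dt = np.maximum(t_min, t0) - t0
    return np.column_stack([np.exp(-np.outer(dt, rates)), np.ones_like(t_min)])


def fit_mtac(
    mtac: TimeActivityCurve,
    t_end_min: float = 30.0,
    n_starts: int = 10,
    n_refine: int = 3,
) -> TriExpFit:
    """Fit a mediastinal curve with a three-phase exponential.

    The fit runs from the observed peak frame through ``t_end_min``, weighted
    by frame duration.  Amplitudes, rates and the constant are constrained
    non-negative; the peak offset ``t0`` is co-estimated within one frame of
    the observed peak midpoint.  Multi-start over log-spaced rate scalings
    (``n_starts`` candidates, amplitudes solved by non-negative least squares)
    guards against local minima; the ``n_refine`` best starts are polished
    with bounded least squares.
    """
    mids = mtac.schedule.mid_min
    vmax = float(mtac.values.max())
    tied = np.nonzero(mtac.values >= vmax - 1e-12 * max(abs(vmax), 1.0))[0]
    # the fit starts at the earliest frame attaining the maximum; the peak
    # offset may sit anywhere under the (possibly flat) observed maximum
    peak_idx = int(tied[0])
    t_peak = float(mids[peak_idx])
    mask = (mids >= t_peak - 1e-12) & (mids <= t_end_min)
    if int(mask.sum()) < 8:
        raise ValueError("need at least 8 frames between the peak and t_end_min")
    t = mids[mask]
    y = mtac.values[mask]
    w = mtac.schedule.duration_min[mask]
    sw = np.sqrt(w)
    t0_init = float(mids[int(tied[-1])])
    t0_lo = t_peak - float(mtac.schedule.duration_min[peak_idx])
    t0_hi = t0_init + float(mtac.schedule.duration_min[int(tied[-1])])

    # screen rate scalings with non-negative linear solves for (A1..A3, C)
    candidates = []
    for f in np.logspace(-0.6, 0.6, n_starts):
        rates = _BASE_RATES * f
        M = _design_matrix(t, rates, t0_init)
        coef, _ = nnls(M * sw[:, None], y * sw)
        resid = sw * (M @ coef - y)
        candidates.append((float(resid @ resid), rates, coef))
    candidates.sort(key=lambda c: c[0])

    def residual(theta: np.ndarray) -> np.ndarray:
        amps, rates, const, t0 = theta[:3], theta[3:6], theta[6], theta[7]
        dt = np.maximum(t, t0) - t0
        model = const + np.exp(-np.outer(dt, rates)) @ amps
        return sw * (model - y)

    lb = np.array([0.0] * 7 + [t0_lo])
    ub = np.array([np.inf] * 7 + [t0_hi])
    best = None
    for wssr0, rates, coef in candidates[:n_refine]:
        theta0 = np.concatenate([coef[:3], rates, [coef[3], t0_init]])
        theta0 = np.clip(theta0, lb, np.minimum(ub, 1e12))
        sol = least_squares(
            residual, theta0, bounds=(lb, ub), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        wssr = float(sol.fun @ sol.fun)
        if best is None or wssr < best[0]:
            best = (wssr, sol)
    wssr, sol = best
    theta = sol.x
    amps, rates, const, t0 = theta[:3].copy(), theta[3:6].copy(), float(theta[6]), float(theta[7])
    # canonical form: a component with no variation over the fit window
    # (zero rate, or t0 pinned at the window end) is a constant — fold it in
    span = max(t[-1] - t0, 0.0)
    variation = amps * (1.0 - np.exp(-rates * span))
    fold = variation < 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    if fold.any():
        const += float(amps[fold].sum())
        amps[fold] = 0.0
    return TriExpFit(
        t0_min=t0,
        amplitudes=amps,
        rates_per_min=rates,
        constant=const,
        fit_window_min=(t_peak, float(t_end_min)),
        wssr=wssr,
        converged=bool(sol.success),
    )


def build_pif(
    mfit: TriExpFit, corrections: CorrectionCurves, schedule: FrameSchedule
) -> TimeActivityCurve:
    """Evaluate the corrected plasma input function on a frame schedule."""
    pif = ParametricPIF(mfit, corrections)
    return TimeActivityCurve(
        schedule=schedule,
        values=pif(schedule.mid_min),
        roi_role="plasma_input",
        decay_corrected=True,
    )


def build_ttac(htac: TimeActivityCurve, mfit: TriExpFit) -> TimeActivityCurve:
    """Tissue curve: heart curve minus the fitted mediastinal curve."""
    if htac.roi_role != "heart":
        raise ValueError("build_ttac expects a heart curve")
    values = htac.values - mfit(htac.schedule.mid_min)
    return TimeActivityCurve(
        schedule=htac.schedule,
        values=values,
        roi_role="tissue",
        decay_corrected=htac.decay_corrected,
    )
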