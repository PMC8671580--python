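"""One-tissue compartment modelling of myocardial tracer curves.

Forward model
-------------
The tissue curve is driven by the plasma input function (PIF)::

    tTAC(t) = [PIF (*) iUp * exp(-iLoss * t)](t) + iNs * PIF(t)

where ``(*)`` is convolution, ``iUp`` (1/min) is the unidirectional uptake
rate into vesicular trapping, ``iLoss`` (1/min) the fractional loss rate of
trapped tracer, and ``iNs`` (unitless) the non-specific interstitial
distribution fraction.  The two-parameter variant (1T2P) omits the ``iNs``
term; the three-parameter model is 1T3P.

Numerics
--------
The convolution is evaluated on a uniform fine grid (default 1 s) with the
exact recursive update for exponential kernels
(``y_{k+1} = y_k * exp(-iLoss*dt) + trapezoid source``), then reduced to frame
values by within-frame averaging — midpoint sampling is available for speed.
Fitting is frame-duration-weighted nonlinear least squares.  Because the
model is linear in ``(iUp, iNs)`` at fixed ``iLoss``, the fit profiles the
linear coefficients out (weighted linear solve) and optimises the single
nonlinear parameter ``iLoss`` by a deterministic coarse grid plus bounded
scalar minimisation.  Estimates are deliberately *unconstrained*: negative
estimates are meaningful quality flags (counted as ``NegCnt`` in truncation
summaries) rather than errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

from .tac import FrameSchedule, TimeActivityCurve

#: Truncation end-times studied for scan-duration optimisation (minutes).
TRUNCATION_END_TIMES_MIN = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 105.0, 195.0)

#: Floor applied to a numerically perfect fit before taking log(WSSR).
WSSR_FLOOR = 1e-12

_COARSE_LOSSES = (
    -0.1, -0.05, -0.02, -0.005, 0.0, 0.005, 0.01, 0.02,
    0.035, 0.05, 0.08, 0.12, 0.2, 0.35, 0.6,
)


def information_criteria(n: int, p: int, wssr: float) -> tuple[float, float]:
    """Akaike and Schwarz information criteria for a least-squares fit.

    ``AIC = N*ln(WSSR) + 2p`` and ``SIC = N*ln(WSSR) + p*ln(N)`` with ``N``
    the number of fitted frames and ``p`` the parameter count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if wssr <= 0:
        raise ValueError("WSSR must be positive (perfect fits are floored upstream)")
    return n * math.log(wssr) + 2.0 * p, n * math.log(wssr) + p * math.log(n)


@dataclass
class KineticFit:
    """Result of a 1T2P/1T3P weighted nonlinear least-squares fit."""

    model: str  # "1T2P" or "1T3P"
    iUp: float  # 1/min
    iLoss: float  # 1/min
    iNs: float  # unitless; 0.0 and unreported for 1T2P
    wssr: float
    n_frames: int
    n_params: int
    aic: float
    sic: float
    fit_window_min: tuple[float, float]
    converged: bool = True
    degenerate: bool = False  # perfect/flat fit, parameters unidentifiable

    def to_record(self) -> dict:
        idx = derive_indices(self)
        return {
            "model": self.model,
            "t_end_min": self.fit_window_min[1],
            "iUp": self.iUp,
            "iLoss": self.iLoss,
            "iNs": self.iNs if self.model == "1T3P" else np.nan,
            "ratio": idx.ratio,
            "half_life_min": idx.half_life_min,
            "wssr": self.wssr,
            "n_frames": self.n_frames,
            "aic": self.aic,
            "sic": self.sic,
            "converged": self.converged,
        }


@dataclass
class IndexSet:
    """Turnover indices derived from a kinetic fit.

    ``ratio = iUp/iLoss`` and ``half_life = 0.693/iLoss`` (the literal 0.693
    as conventionally printed, not ln 2) are undefined when ``iLoss <= 0``;
    they are then NaN with ``defined = False``.
    """

    iUp: float
    iLoss: float
    iNs: float
    ratio: float
    half_life_min: float
    defined: bool


def derive_indices(fit: KineticFit) -> IndexSet:
    if fit.iLoss > 0:
        return IndexSet(
            fit.iUp, fit.iLoss, fit.iNs,
            ratio=fit.iUp / fit.iLoss,
            half_life_min=0.693 / fit.iLoss,
            defined=True,
        )
    return IndexSet(fit.iUp, fit.iLoss, fit.iNs, np.nan, np.nan, defined=False)


# ---------------------------------------------------------------------------
# fine-grid machinery

def _pif_on_grid(pif, t_min: np.ndarray) -> np.ndarray:
    if callable(pif):
        return np.asarray(pif(t_min), dtype=float)
    if isinstance(pif, TimeActivityCurve):
        return np.interp(t_min, pif.schedule.mid_min, pif.values)
    raise TypeError("pif must be callable in minutes or a TimeActivityCurve")


def _convolve_exp_unit(p_mid: np.ndarray, dt_min: float, iloss: float) -> np.ndarray:
    """[p (*) exp(-iloss*t)] at grid nodes for unit amplitude.

    ``p_mid`` holds the input sampled at grid-interval midpoints; each
    interval is propagated with the exact constant-segment solution
    ``c_k = c_{k-1}*exp(-iloss*dt) + p_k*(1-exp(-iloss*dt))/iloss``, so the
    result is exact (not just second-order) for inputs that are piecewise
    constant on the grid."""
    a = math.exp(-iloss * dt_min)
    g = dt_min if abs(iloss * dt_min) < 1e-12 else (1.0 - a) / iloss
    u = np.empty(p_mid.size + 1)
    u[0] = 0.0
    u[1:] = g * p_mid
    return lfilter([1.0], [1.0, -a], u)


def _frame_indices(schedule: FrameSchedule, dt_s: float, n_grid: int):
    i0 = np.clip(np.rint(schedule.start_s / dt_s).astype(int), 0, n_grid - 1)
    i1 = np.clip(np.rint(schedule.end_s / dt_s).astype(int), 0, n_grid - 1)
    return i0, i1


def _frame_means(grid_vals: np.ndarray, i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(grid_vals)])
    return (cs[i1 + 1] - cs[i0]) / (i1 + 1 - i0)


def forward_model(
    pif,
    iUp: float,
    iLoss: float,
    iNs: float,
    schedule: FrameSchedule,
    dt_s: float = 1.0,
    frame_average: bool = True,
) -> TimeActivityCurve:
    """Evaluate the one-tissue forward model on a frame schedule.

    ``pif`` is either a callable of minutes (parametric input function) or a
    :class:`TimeActivityCurve` (interpolated at grid times).  Negative
    ``iLoss`` is accepted — the fit explores it.
    """
    t_end_s = float(schedule.end_s[-1])
    n = int(round(t_end_s / dt_s)) + 1
    t_min = np.arange(n) * (dt_s / 60.0)
    p = _pif_on_grid(pif, t_min)
    p_mid = _pif_on_grid(pif, (np.arange(n - 1) + 0.5) * (dt_s / 60.0))
    conv = iUp * _convolve_exp_unit(p_mid, dt_s / 60.0, iLoss)
    total = conv + iNs * p
    i0, i1 = _frame_indices(schedule, dt_s, n)
    if frame_average:
        values = _frame_means(total, i0, i1)
    else:
        mid_idx = np.clip(np.rint(schedule.mid_s / dt_s).astype(int), 0, n - 1)
        values = total[mid_idx]
    return TimeActivityCurve(schedule, values, roi_role="tissue", decay_corrected=True)


# ---------------------------------------------------------------------------
# estimator

class OneTissueModel(BaseEstimator):
    """One-tissue compartment model estimator (scikit-learn style).

    Parameters
    ----------
    model : {"1T3P", "1T2P"}
        Whether the non-specific distribution term ``iNs`` is estimated.
    t_start_min, t_end_min : float
        Fit window; frames with midpoints outside it are excluded.  The
        default start of 1 min reflects the assumed sub-minute equilibration
        of the interstitial compartment with plasma.
    dt_s : float
        Fine-grid step for the convolution, seconds.
    weighting : {"duration", "duration_over_value"}
        Residual weights: proportional to frame duration (default), or to
        duration/value as an approximate Poisson alternative.
    frame_average : bool
        Compare frame-averaged model values against the data (default) or
        midpoint samples.

    Attributes
    ----------
    iUp_, iLoss_, iNs_ : float
        Estimated rate constants (unconstrained; may be negative).
    result_ : KineticFit
        Full fit record including WSSR, AIC/SIC and flags.
    """

    def __init__(
        self,
        model: str = "1T3P",
        t_start_min: float = 1.0,
        t_end_min: float = 30.0,
        dt_s: float = 1.0,
        weighting: str = "duration",
        frame_average: bool = True,
        coarse_losses: Sequence[float] = _COARSE_LOSSES,
    ):
        self.model = model
        self.t_start_min = t_start_min
        self.t_end_min = t_end_min
        self.dt_s = dt_s
        self.weighting = weighting
        self.frame_average = frame_average
        self.coarse_losses = coarse_losses

    # -- internals --------------------------------------------------------
    def _weights(self, schedule: FrameSchedule, mask: np.ndarray, y: np.ndarray):
        w = schedule.duration_min[mask].copy()
        if self.weighting == "duration_over_value":
            w = w / np.maximum(np.abs(y), 1e-6)
        elif self.weighting != "duration":
            raise ValueError(f"unknown weighting {self.weighting!r}")
        return w

    def fit(self, ttac: TimeActivityCurve, pif) -> "OneTissueModel":
        if self.model not in ("1T2P", "1T3P"):
            raise ValueError(f"unknown model {self.model!r}")
        p_count = 3 if self.model == "1T3P" else 2
        schedule = ttac.schedule
        mask = schedule.window_mask(self.t_start_min, self.t_end_min)
        n_fit = int(mask.sum())
        if n_fit < p_count + 1:
            raise ValueError(
                f"{n_fit} frames in window; need at least {p_count + 1}"
            )
        y = ttac.values[mask]
        w = self._weights(schedule, mask, y)

        t_end_s = float(schedule.end_s[mask][-1])
        n_grid = int(round(t_end_s / self.dt_s)) + 1
        t_min = np.arange(n_grid) * (self.dt_s / 60.0)
        p_grid = _pif_on_grid(pif, t_min)
        p_mid_grid = _pif_on_grid(pif, (np.arange(n_grid - 1) + 0.5) * (self.dt_s / 60.0))
        i0, i1 = _frame_indices(schedule, self.dt_s, n_grid)
        i0, i1 = i0[mask], i1[mask]
        if self.frame_average:
            pif_frames = _frame_means(p_grid, i0, i1)
        else:
            mid_idx = np.clip(
                np.rint(schedule.mid_s[mask] / self.dt_s).astype(int), 0, n_grid - 1
            )
            pif_frames = p_grid[mid_idx]
            mid_cache = mid_idx

        dt_min = self.dt_s / 60.0

        def solve(iloss: float):
            basis = _convolve_exp_unit(p_mid_grid, dt_min, iloss)
            if self.frame_average:
                b1 = _frame_means(basis, i0, i1)
            else:
                b1 = basis[mid_cache]
            if self.model == "1T3P":
                X = np.column_stack([b1, pif_frames])
            else:
                X = b1[:, None]
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            resid = y - X @ coef
            return float(np.sum(w * resid * resid)), coef

        cands = list(self.coarse_losses)
        wssrs = [solve(c)[0] for c in cands]
        k = int(np.argmin(wssrs))
        # widen the bracket if the coarse minimum sits on an edge
        while k == 0:
            cands.insert(0, cands[0] - 0.25)
            wssrs.insert(0, solve(cands[0])[0])
            k = int(np.argmin(wssrs))
            if cands[0] < -5.0:
                break
        while k == len(cands) - 1:
            cands.append(cands[-1] * 2.0 if cands[-1] > 0 else 0.5)
            wssrs.append(solve(cands[-1])[0])
            k = int(np.argmin(wssrs))
            if cands[-1] > 50.0:
                break
        lo = cands[max(k - 1, 0)]
        hi = cands[min(k + 1, len(cands) - 1)]
        res = minimize_scalar(
            lambda x: solve(x)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        iloss = float(res.x)
        wssr, coef = solve(iloss)
        if wssrs[k] < wssr:  # scalar search never worsens the coarse optimum
            iloss = cands[k]
            wssr, coef = solve(iloss)

        iup = float(coef[0])
        ins = float(coef[1]) if self.model == "1T3P" else 0.0
        degenerate = wssr < WSSR_FLOOR
        aic, sic = information_criteria(n_fit, p_count, max(wssr, WSSR_FLOOR))
        self.iUp_ = iup
        self.iLoss_ = iloss
        self.iNs_ = ins
        self.result_ = KineticFit(
            model=self.model,
            iUp=iup,
            iLoss=iloss,
            iNs=ins,
            wssr=wssr,
            n_frames=n_fit,
            n_params=p_count,
            aic=aic,
            sic=sic,
            fit_window_min=(self.t_start_min, self.t_end_min),
            converged=bool(getattr(res, "success", True)),
            degenerate=degenerate,
        )
        self._pif = pif
        return self

    def predict(self, schedule: FrameSchedule | None = None) -> TimeActivityCurve:
        """Model tissue curve on ``schedule`` (default: the fitted window's
        schedule is not stored; a schedule must be given)."""
        if not hasattr(self, "result_"):
            raise AttributeError("model is not fitted")
        if schedule is None:
            raise ValueError("predict requires a FrameSchedule")
        return forward_model(
            self._pif, self.iUp_, self.iLoss_, self.iNs_, schedule,
            dt_s=self.dt_s, frame_average=self.frame_average,
        )


def fit_kinetics(
    ttac: TimeActivityCurve,
    pif,
    model: str = "1T3P",
    t_start_min: float = 1.0,
    t_end_min: float = 30.0,
    **options,
) -> KineticFit:
    """Functional wrapper around :class:`OneTissueModel`."""
    est = OneTissueModel(
        model=model, t_start_min=t_start_min, t_end_min=t_end_min, **options
    )
    est.fit(ttac, pif)
    return est.result_


# ---------------------------------------------------------------------------
# truncation study

_PARAM_COLS = {"1T3P": ("iUp", "iLoss", "iNs"), "1T2P": ("iUp", "iLoss")}


def truncation_study(
    patients: Iterable[tuple[TimeActivityCurve, object]],
    end_times_min: Sequence[float] = TRUNCATION_END_TIMES_MIN,
    models: Sequence[str] = ("1T3P", "1T2P"),
    t_start_min: float = 1.0,
    **options,
) -> dict[str, pd.DataFrame]:
    """Scan-truncation study: refit every patient at each end time.

    Returns one summary table per model, indexed by end time, with the mean
    and SD of each index, mean AIC/SIC, and NegCnt — the number of patients
    whose estimate of a given parameter came out negative.  Ratio and
    half-life statistics are computed over patients with ``iLoss > 0`` only.
    """
    patients = list(patients)
    out: dict[str, pd.DataFrame] = {}
    for model in models:
        rows = []
        for t_end in end_times_min:
            fits = [
                fit_kinetics(ttac, pif, model=model, t_start_min=t_start_min,
                             t_end_min=t_end, **options)
                for ttac, pif in patients
            ]
            row: dict[str, float] = {"t_end_min": t_end}
            for name in _PARAM_COLS[model]:
                vals = np.array([getattr(f, name) for f in fits])
                row[f"{name}_mean"] = vals.mean()
                row[f"{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
                row[f"negcnt_{name}"] = int(np.sum(vals < 0))
            idx = [derive_indices(f) for f in fits]
            ratios = np.array([i.ratio for i in idx if i.defined])
            hls = np.array([i.half_life_min for i in idx if i.defined])
            row["ratio_mean"] = ratios.mean() if ratios.size else np.nan
            row["ratio_sd"] = ratios.std(ddof=1) if ratios.size > 1 else np.nan
            row["half_life_mean"] = hls.mean() if hls.size else np.nan
            row["half_life_sd"] = hls.std(ddof=1) if hls.size > 1 else np.nan
            row["aic_mean"] = float(np.mean([f.aic for f in fits]))
            row["sic_mean"] = float(np.mean([f.sic for f in fits]))
            rows.append(row)
        out[model] = pd.DataFrame(rows).set_index("t_end_min")
    return out
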