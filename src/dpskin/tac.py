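"""Frame schedules and time-activity curves for dynamic planar scintigraphy.

Conventions used throughout the package:

* Frame timestamps are **seconds from injection**; frames are half-open
  intervals ``[start, start + duration)``.  Gaps between scan blocks are
  allowed and carry no data.
* Curve values are **mean counts per pixel per second** (a rate), one value
  per frame.  Rates make frames of different duration (2 s bolus frames vs
  300 s static frames) directly comparable.
* Model evaluation against measured frames uses frame midpoints unless
  frame-averaging is requested explicitly (see :mod:`dpskin.kinetics`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Physical half-life of 123-iodine, minutes (standard nuclide value).
I123_HALF_LIFE_MIN = 13.2235 * 60.0

ROI_ROLES = ("heart", "mediastinum", "tissue", "plasma_input")

#: Roles whose curves must be non-negative (tissue curves may dip below zero
#: after mediastinal subtraction).
_NONNEGATIVE_ROLES = ("mediastinum", "plasma_input")

TAC_CSV_COLUMNS = [
    "patient_id",
    "roi",
    "frame_index",
    "start_s",
    "duration_s",
    "value_cps_per_pixel",
    "decay_corrected",
]


@dataclass(frozen=True, eq=False)
class FrameSchedule:
    """An ordered sequence of acquisition frames on an irregular grid.

    Parameters
    ----------
    start_s : array-like
        Frame start times in seconds from injection, strictly increasing.
    duration_s : array-like
        Frame durations in seconds, all positive.  Frames must not overlap;
        gaps between scan blocks are allowed.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.atleast_1d(np.asarray(self.start_s, dtype=float))
        dur = np.atleast_1d(np.asarray(self.duration_s, dtype=float))
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("a schedule needs at least one frame")
        if np.any(dur <= 0):
            bad = np.nonzero(dur <= 0)[0]
            raise ValueError(f"non-positive frame duration at index {bad[0]}")
        if np.any(np.diff(start) <= 0):
            bad = np.nonzero(np.diff(start) <= 0)[0]
            raise ValueError(f"frame starts not strictly increasing at index {bad[0] + 1}")
        overlap = start[1:] < start[:-1] + dur[:-1] - 1e-9
        if np.any(overlap):
            bad = np.nonzero(overlap)[0]
            raise ValueError(f"overlapping frames at indices {bad[0]} and {bad[0] + 1}")
        start.setflags(write=False)
        dur.setflags(write=False)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.duration_s.sum())

    def window_mask(self, t_start_min: float, t_end_min: float) -> np.ndarray:
        """Boolean mask of frames whose midpoints fall inside a time window."""
        mid = self.mid_min
        return (mid >= t_start_min) & (mid <= t_end_min)

    def same_grid(self, other: "FrameSchedule", tol_s: float = 1e-9) -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.start_s, other.start_s, atol=tol_s, rtol=0)
            and np.allclose(self.duration_s, other.duration_s, atol=tol_s, rtol=0)
        )


@dataclass(eq=False)
class TimeActivityCurve:
    """Mean counts/pixel/second per frame for one region of interest."""

    schedule: FrameSchedule
    values: np.ndarray
    roi_role: str
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {vals.shape} does not match "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("curve values must be finite")
        if self.roi_role not in ROI_ROLES:
            raise ValueError(f"unknown roi_role {self.roi_role!r}; expected one of {ROI_ROLES}")
        if self.roi_role in _NONNEGATIVE_ROLES and np.any(vals < 0):
            raise ValueError(f"{self.roi_role} curves must be non-negative")
        self.values = vals

    def with_values(self, values: np.ndarray, **changes) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


def _block(start_s: float, n: int, frame_s: float) -> tuple[np.ndarray, np.ndarray]:
    starts = start_s + frame_s * np.arange(n)
    return starts, np.full(n, float(frame_s))


def standard_schedule(kind: str = "full") -> FrameSchedule:
    """Return a standard acquisition schedule.

    ``scan1`` is the 30-min dynamic sequence started at injection
    (30 x 2 s + 40 x 6 s + 75 x 20 s).  ``scan2`` and ``scan3`` are 3 x 300 s
    static blocks started at 90 and 180 min; ``full`` concatenates all three,
    ending at 195 min so that the delayed heart-to-mediastinum window
    (190-195 min) is covered.
    """
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    if kind == "scan1":
        blocks = [_block(0.0, 30, 2.0), _block(60.0, 40, 6.0), _block(300.0, 75, 20.0)]
    elif kind == "scan2":
        blocks = [_block(90 * 60.0, 3, 300.0)]
    elif kind == "scan3":
        blocks = [_block(180 * 60.0, 3, 300.0)]
    elif kind == "full":
        for sub in ("scan1", "scan2", "scan3"):
            s = standard_schedule(sub)
            blocks.append((s.start_s, s.duration_s))
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    start = np.concatenate([b[0] for b in blocks])
    dur = np.concatenate([b[1] for b in blocks])
    return FrameSchedule(start, dur)


def decay_apply(
    tac: TimeActivityCurve, half_life_min: float = I123_HALF_LIFE_MIN
) -> TimeActivityCurve:
    """Impose physical decay on a decay-corrected curve (inverse of
    :func:`decay_correct`); used by the simulator and washout-rate checks."""
    if not tac.decay_corrected:
        raise ValueError("curve is already on the decayed (measured) scale")
    if half_life_min <= 0:
        raise ValueError("half_life_min must be positive")
    factor = 0.5 ** (tac.schedule.mid_min / half_life_min)
    return tac.with_values(tac.values * factor, decay_corrected=False)


def decay_correct(
    tac: TimeActivityCurve, half_life_min: float = I123_HALF_LIFE_MIN
) -> TimeActivityCurve:
    """Decay-correct a measured curve to injection time.

    Each frame value is multiplied by ``2**(t_mid / half_life)`` with ``t_mid``
    the frame midpoint.
    """
    if tac.decay_corrected:
        raise ValueError("curve is already decay-corrected")
    if half_life_min <= 0:
        raise ValueError("half_life_min must be positive")
    factor = 2.0 ** (tac.schedule.mid_min / half_life_min)
    return tac.with_values(tac.values * factor, decay_corrected=True)


def write_tac_table(curves: dict[tuple[str, str], TimeActivityCurve], path) -> None:
    """Write curves to the TAC CSV dialect.

    ``curves`` maps ``(patient_id, roi_role)`` to a curve.  The round trip
    through :func:`read_tac_table` is lossless (values printed at full
    precision).
    """
    rows = []
    for (pid, roi), tac in curves.items():
        sched = tac.schedule
        for j in range(sched.n_frames):
            rows.append(
                {
                    "patient_id": pid,
                    "roi": roi,
                    "frame_index": j,
                    "start_s": repr(float(sched.start_s[j])),
                    "duration_s": repr(float(sched.duration_s[j])),
                    "value_cps_per_pixel": repr(float(tac.values[j])),
                    "decay_corrected": tac.decay_corrected,
                }
            )
    pd.DataFrame(rows, columns=TAC_CSV_COLUMNS).to_csv(path, index=False)


def read_tac_table(path) -> dict[tuple[str, str], TimeActivityCurve]:
    """Read a TAC CSV file into ``{(patient_id, roi_role): curve}``.

    Curves of one patient that share identical frame grids share a single
    :class:`FrameSchedule` object.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TAC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC table missing columns: {missing}")
    if df["roi"].isna().any():
        bad = df.index[df["roi"].isna()][0]
        raise ValueError(f"role-less row at index {bad}")
    out: dict[tuple[str, str], TimeActivityCurve] = {}
    schedules: dict[str, list[FrameSchedule]] = {}
    for (pid, roi), grp in df.groupby(["patient_id", "roi"], sort=False):
        grp = grp.sort_values("frame_index")
        try:
            sched = FrameSchedule(
                grp["start_s"].to_numpy(float), grp["duration_s"].to_numpy(float)
            )
        except ValueError as err:
            raise ValueError(
                f"invalid frames for patient {pid!r} roi {roi!r} "
                f"(rows {list(grp.index[:3])}...): {err}"
            ) from err
        # reuse one schedule object per identical grid within a patient
        for prev in schedules.setdefault(str(pid), []):
            if prev.same_grid(sched):
                sched = prev
                break
        else:
            schedules[str(pid)].append(sched)
        flag = grp["decay_corrected"].to_numpy()
        out[(str(pid), str(roi))] = TimeActivityCurve(
            schedule=sched,
            values=grp["value_cps_per_pixel"].to_numpy(float),
            roi_role=str(roi),
            decay_corrected=bool(flag[0]),
        )
    return out
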