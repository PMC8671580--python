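"""Synthetic patient cohorts with known kinetic ground truth.

Real dynamic planar MIBG data are not publicly available, so every pipeline
stage is exercised on simulated patients whose statistical structure mirrors
the clinical setting: class-conditional distributions of the kinetic
parameters for disease subgroups (Parkinson's disease with/without probable
RBD, dementia with Lewy bodies) and a non-diseased group, a bolus-like
tri-exponential mediastinal template with slow late clearance, the
population-based blood/metabolite corrections, and counting noise whose
variance scales with rate/duration (the ROI-mean Gaussian approximation of
Poisson counting statistics; an exact-Poisson mode is available).

Parameter sampling is moment-matched: iLoss and the ratio iUp/iLoss are
log-normal with the configured group mean and SD (iUp = ratio * iLoss), and
iNs is a zero-truncated normal.  Group calibration anchors and their
provenance are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .input_function import CorrectionCurves, ParametricPIF, TriExpFit
from .kinetics import forward_model
from .tac import FrameSchedule, TimeActivityCurve, standard_schedule, write_tac_table

logger = logging.getLogger(__name__)

LBD_SUBGROUPS = ("PD_pRBDpos", "PD_pRBDneg", "DLB")
GROUPS = LBD_SUBGROUPS + ("nonLBD",)

COHORT_CSV_COLUMNS = [
    "patient_id",
    "class_label",
    "subgroup",
    "true_iUp",
    "true_iLoss",
    "true_iNs",
    "seed",
]


@dataclass(frozen=True)
class GroupParams:
    """Class-conditional distribution of the true kinetic parameters."""

    n: int
    iloss_mean: float
    iloss_sd: float
    ratio_mean: float  # iUp/iLoss
    ratio_sd: float
    ins_mean: float = 0.21
    ins_sd: float = 0.11

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for sd in (self.iloss_sd, self.ratio_sd, self.ins_sd):
            if sd <= 0:
                raise ValueError("all SDs must be positive")
        if not (0.0 < self.iloss_mean < 0.2):
            raise ValueError("iloss_mean outside physiologic range (0, 0.2)")


#: Subgroup sizes and (mean, SD) anchors for the three disease subgroups;
#: the non-diseased group is a package calibration choice (see methods note).
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "PD_pRBDpos": GroupParams(n=35, iloss_mean=0.0647, iloss_sd=0.0170,
                              ratio_mean=1.17, ratio_sd=0.47),
    "PD_pRBDneg": GroupParams(n=61, iloss_mean=0.0557, iloss_sd=0.0129,
                              ratio_mean=2.30, ratio_sd=1.67),
    "DLB": GroupParams(n=9, iloss_mean=0.0683, iloss_sd=0.0247,
                       ratio_mean=1.09, ratio_sd=0.68),
    "nonLBD": GroupParams(n=61, iloss_mean=0.038, iloss_sd=0.007,
                          ratio_mean=3.5, ratio_sd=1.0),
}

#: Mediastinal template: bolus-like peak with slow late clearance.
DEFAULT_MTAC_TEMPLATE = dict(
    amplitudes=(40.0, 8.0, 2.0),  # cps/pixel
    rates_per_min=(2.0, 0.15, 0.01),
    constant=0.8,
    t0_min=0.5,
)


@dataclass
class CohortConfig:
    """Cohort generator settings.

    ``noise_level`` scales the counting-noise standard deviation
    ``sigma = noise_level * sqrt(rate / duration_s)``; 0.05 corresponds to
    Poisson noise on a per-pixel rate averaged over a few hundred ROI pixels.
    """

    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    noise_level: float = 0.05
    noise_model: str = "gaussian"  # or "poisson"
    mtac_template: dict = field(default_factory=lambda: dict(DEFAULT_MTAC_TEMPLATE))
    mtac_jitter_frac: float = 0.10
    t0_jitter_min: float = 0.05
    corrections: CorrectionCurves = field(default_factory=CorrectionCurves)
    master_seed: int = 20211214

    def __post_init__(self) -> None:
        for name in self.groups:
            if name not in GROUPS:
                raise ValueError(f"unknown group {name!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


@dataclass
class PatientRecord:
    """One simulated patient: labels, ground truth and reproducibility seed."""

    patient_id: str
    class_label: str  # "LBD" or "nonLBD"
    subgroup: str  # one of LBD_SUBGROUPS, or "none"
    true_iUp: float
    true_iLoss: float
    true_iNs: float
    true_mtac: TriExpFit
    noise_level: float
    seed: int

    def __post_init__(self) -> None:
        if self.subgroup != "none" and self.class_label != "LBD":
            raise ValueError("a disease subgroup implies class_label == 'LBD'")


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal parameters matching an arithmetic mean and SD exactly."""
    var_ratio = (sd / mean) ** 2
    sigma2 = np.log1p(var_ratio)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def sample_true_params(
    config: CohortConfig, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorised draw of ``n`` true parameter triples for one group."""
    gp = config.groups[group]
    mu_l, sg_l = _lognormal_mu_sigma(gp.iloss_mean, gp.iloss_sd)
    mu_r, sg_r = _lognormal_mu_sigma(gp.ratio_mean, gp.ratio_sd)
    iloss = rng.lognormal(mu_l, sg_l, size=n)
    ratio = rng.lognormal(mu_r, sg_r, size=n)
    # zero-truncated normal for the interstitial fraction
    ins = rng.normal(gp.ins_mean, gp.ins_sd, size=n)
    while np.any(ins <= 0):
        bad = ins <= 0
        ins[bad] = rng.normal(gp.ins_mean, gp.ins_sd, size=int(bad.sum()))
    return pd.DataFrame(
        {"iUp": ratio * iloss, "iLoss": iloss, "iNs": ins, "ratio": ratio}
    )


def _jitter_mtac(config: CohortConfig, rng: np.random.Generator) -> TriExpFit:
    tmpl = config.mtac_template
    f = config.mtac_jitter_frac
    amps = np.asarray(tmpl["amplitudes"], float) * rng.lognormal(0.0, f, 3)
    rates = np.asarray(tmpl["rates_per_min"], float) * rng.lognormal(0.0, f, 3)
    const = float(tmpl["constant"]) * rng.lognormal(0.0, f)
    t0 = float(tmpl["t0_min"]) + rng.uniform(-config.t0_jitter_min, config.t0_jitter_min)
    return TriExpFit(t0_min=max(t0, 0.0), amplitudes=amps, rates_per_min=rates,
                     constant=const)


def sample_patient(
    config: CohortConfig, group: str, seed: int, patient_id: str | None = None
) -> PatientRecord:
    """Draw one patient's ground truth (kinetic parameters and mediastinal
    template); deterministic in ``seed``."""
    if group not in config.groups:
        raise ValueError(f"group {group!r} not in config")
    rng = np.random.default_rng(seed)
    params = sample_true_params(config, group, 1, rng).iloc[0]
    mtac = _jitter_mtac(config, rng)
    is_lbd = group in LBD_SUBGROUPS
    return PatientRecord(
        patient_id=patient_id or f"{group}_{seed}",
        class_label="LBD" if is_lbd else "nonLBD",
        subgroup=group if is_lbd else "none",
        true_iUp=float(params["iUp"]),
        true_iLoss=float(params["iLoss"]),
        true_iNs=float(params["iNs"]),
        true_mtac=mtac,
        noise_level=config.noise_level,
        seed=int(seed),
    )


def _add_noise(
    values: np.ndarray,
    schedule: FrameSchedule,
    noise_level: float,
    noise_model: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise_level == 0:
        return values.copy()
    if noise_model == "poisson":
        # noise_level = 1/sqrt(n_eff): rate averaged over n_eff pixels
        n_eff = 1.0 / noise_level**2
        counts = np.maximum(values, 0.0) * schedule.duration_s * n_eff
        return rng.poisson(counts) / (schedule.duration_s * n_eff)
    sigma = noise_level * np.sqrt(np.maximum(values, 0.0) / schedule.duration_s)
    return values + rng.normal(0.0, 1.0, size=values.shape) * sigma


def simulate_scan(
    record: PatientRecord,
    schedule: FrameSchedule | None = None,
    corrections: CorrectionCurves | None = None,
    noise_model: str = "gaussian",
    seed: int | None = None,
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Simulate decay-corrected heart and mediastinal curves for a patient.

    The mediastinal curve is the patient's tri-exponential template sampled
    at frame midpoints; the plasma input is the template times PBMC/BPR; the
    tissue curve is the one-tissue forward model (frame-averaged); the heart
    curve is tissue + mediastinum.  Counting noise is added independently to
    the heart and mediastinal curves; negative mediastinal values are clipped
    at zero (count logged).
    """
    if schedule is None:
        schedule = standard_schedule("full")
    if corrections is None:
        corrections = CorrectionCurves()
    rng = np.random.default_rng(
        record.seed + 1 if seed is None else seed
    )
    mtac_clean = record.true_mtac(schedule.mid_min)
    pif = ParametricPIF(record.true_mtac, corrections)
    tissue = forward_model(
        pif, record.true_iUp, record.true_iLoss, record.true_iNs, schedule
    ).values
    htac_clean = tissue + mtac_clean

    m_noisy = _add_noise(mtac_clean, schedule, record.noise_level, noise_model, rng)
    h_noisy = _add_noise(htac_clean, schedule, record.noise_level, noise_model, rng)
    n_clip = int(np.sum(m_noisy < 0))
    if n_clip:
        logger.debug("%s: clipped %d negative mediastinal frames", record.patient_id, n_clip)
        m_noisy = np.maximum(m_noisy, 0.0)

    mtac = TimeActivityCurve(schedule, m_noisy, "mediastinum", decay_corrected=True)
    htac = TimeActivityCurve(schedule, h_noisy, "heart", decay_corrected=True)
    return htac, mtac


def generate_cohort(
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TimeActivityCurve]]:
    """Generate the full synthetic cohort (default: 105 LBD + 61 non-LBD).

    Returns the cohort table (labels, subgroups and flagged ground truth) and
    the simulated curves keyed ``(patient_id, roi)``.  With ``out_dir`` set,
    writes ``cohort.csv`` and ``tacs.csv``; the TAC file contains no
    ground-truth columns, so downstream diagnostic stages cannot leak truth.
    Fully deterministic in the master seed.
    """
    config = config or CohortConfig()
    master = config.master_seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rows = []
    tacs: dict[tuple[str, str], TimeActivityCurve] = {}
    schedule = standard_schedule("full")
    pid_no = 0
    for group in GROUPS:
        if group not in config.groups:
            continue
        gp = config.groups[group]
        children = ss.spawn(gp.n)
        for child in children:
            pid_no += 1
            pid = f"P{pid_no:03d}"
            pseed = int(child.generate_state(1)[0] % (2**31 - 1))
            rec = sample_patient(config, group, pseed, patient_id=pid)
            htac, mtac = simulate_scan(
                rec, schedule, config.corrections, config.noise_model
            )
            tacs[(pid, "heart")] = htac
            tacs[(pid, "mediastinum")] = mtac
            rows.append(
                {
                    "patient_id": pid,
                    "class_label": rec.class_label,
                    "subgroup": rec.subgroup,
                    "true_iUp": rec.true_iUp,
                    "true_iLoss": rec.true_iLoss,
                    "true_iNs": rec.true_iNs,
                    "seed": pseed,
                }
            )
    cohort = pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        write_tac_table(tacs, out_dir / "tacs.csv")
    return cohort, tacs
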