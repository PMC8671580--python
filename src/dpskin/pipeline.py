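"""End-to-end orchestration: simulate -> fit -> evaluate.

``analyze_cohort`` runs the full per-patient chain (mediastinal tri-exp fit,
input-function construction, tissue-curve extraction, 1T2P/1T3P kinetic fits
at the configured truncation end times, and the static indices), returning a
tidy results table.  ``evaluate_diagnostics`` consumes that table and the
class labels and produces the diagnostic report: per-index ROC rows with
Youden cut-offs, bootstrap AUC comparisons against the early
heart-to-mediastinum ratio, SMOTE-balanced SVM evaluations, fixed-cutoff
diagnostic odds ratios, and Dunnett subgroup comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, LBD_SUBGROUPS, generate_cohort
from .diagnostics import (
    bootstrap_auc_test,
    diagnostic_odds_ratio,
    dunnett_comparison,
    repeated_svm_evaluation,
    roc_auc,
    smote,
    youden_cutoff,
)
from .input_function import CorrectionCurves, ParametricPIF, build_ttac, fit_mtac
from .kinetics import TRUNCATION_END_TIMES_MIN, fit_kinetics, truncation_study
from .static_indices import DELAYED_WINDOW_MIN, EARLY_WINDOW_MIN, hmr, washout_rate
from .tac import TimeActivityCurve, read_tac_table

logger = logging.getLogger(__name__)

#: Index polarity: True when high values indicate disease.
INDEX_ORIENTATIONS: dict[str, bool] = {
    "iLoss": True,
    "ratio": False,
    "eHMR": False,
    "dHMR": False,
    "WR": True,
}


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; see YAML examples in the README."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    end_times_min: tuple[float, ...] = TRUNCATION_END_TIMES_MIN
    models: tuple[str, ...] = ("1T3P", "1T2P")
    t_start_min: float = 1.0
    weighting: str = "duration"
    svm_kernels: tuple[str, ...] = ("linear", "rbf")
    n_runs: int = 200
    train_frac: float = 0.7
    smote_k: int = 5
    n_boot: int = 2000
    seed: int = 20211214

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort_d = d.pop("cohort", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if cohort_d:
            from .cohort import DEFAULT_GROUPS, GroupParams

            groups = dict(DEFAULT_GROUPS)
            for name, gp in cohort_d.pop("groups", {}).items():
                groups[name] = GroupParams(**gp)
            corr = cohort_d.pop("corrections", None)
            cfg.cohort = CohortConfig(
                groups=groups,
                corrections=CorrectionCurves(**corr) if corr else CorrectionCurves(),
                **cohort_d,
            )
        return cfg

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_patient(
    htac: TimeActivityCurve,
    mtac: TimeActivityCurve,
    corrections: CorrectionCurves,
    end_times_min=(30.0,),
    models=("1T3P", "1T2P"),
    t_start_min: float = 1.0,
    weighting: str = "duration",
):
    """Run the kinetic chain for one patient.

    Returns ``(kinetic_records, static_record, (ttac, pif))``; the mediastinal
    fit extends through the largest requested end time.
    """
    mfit = fit_mtac(mtac, t_end_min=max(end_times_min))
    pif = ParametricPIF(mfit, corrections)
    ttac = build_ttac(htac, mfit)
    kin = []
    for model in models:
        for t_end in end_times_min:
            f = fit_kinetics(
                ttac, pif, model=model, t_start_min=t_start_min,
                t_end_min=t_end, weighting=weighting,
            )
            kin.append(f.to_record())
    static = {"eHMR": hmr(htac, mtac, EARLY_WINDOW_MIN)}
    if htac.schedule.window_mask(*DELAYED_WINDOW_MIN).any():
        static["dHMR"] = hmr(htac, mtac, DELAYED_WINDOW_MIN)
        static["WR"] = washout_rate(htac, mtac)
    else:
        static["dHMR"] = np.nan
        static["WR"] = np.nan
    return kin, static, (ttac, pif)


def analyze_cohort(
    tacs: dict[tuple[str, str], TimeActivityCurve],
    corrections: CorrectionCurves | None = None,
    end_times_min=(30.0,),
    models=("1T3P", "1T2P"),
    t_start_min: float = 1.0,
    weighting: str = "duration",
) -> pd.DataFrame:
    """Fit every patient in a TAC collection.

    Returns one row per (patient, model, end time) with the kinetic record
    and the patient's static indices repeated on each row.  Per-patient
    failures are logged and skipped so one bad curve cannot abort a cohort.
    """
    corrections = corrections or CorrectionCurves()
    patient_ids = sorted({pid for pid, _ in tacs})
    rows = []
    for pid in patient_ids:
        try:
            htac = tacs[(pid, "heart")]
            mtac = tacs[(pid, "mediastinum")]
        except KeyError as err:
            logger.warning("%s: missing ROI curve %s; skipped", pid, err)
            continue
        try:
            kin, static, _ = analyze_patient(
                htac, mtac, corrections, end_times_min, models,
                t_start_min, weighting,
            )
        except Exception as err:  # pragma: no cover - defensive per-patient guard
            logger.warning("%s: analysis failed (%s); skipped", pid, err)
            continue
        for rec in kin:
            rows.append({"patient_id": pid, **rec, **static})
    return pd.DataFrame(rows)


def cohort_truncation_tables(
    tacs: dict[tuple[str, str], TimeActivityCurve],
    corrections: CorrectionCurves | None = None,
    end_times_min=TRUNCATION_END_TIMES_MIN,
    models=("1T3P", "1T2P"),
    **options,
) -> dict[str, pd.DataFrame]:
    """Truncation summary tables (per model) for a TAC collection."""
    corrections = corrections or CorrectionCurves()
    pairs = []
    for pid in sorted({p for p, _ in tacs}):
        mfit = fit_mtac(tacs[(pid, "mediastinum")], t_end_min=max(end_times_min))
        pif = ParametricPIF(mfit, corrections)
        pairs.append((build_ttac(tacs[(pid, "heart")], mfit), pif))
    return truncation_study(pairs, end_times_min, models, **options)


def _index_frame(results: pd.DataFrame, labels: pd.DataFrame,
                 t_end_min: float = 30.0, model: str = "1T3P") -> pd.DataFrame:
    sel = results[(results["model"] == model) & (results["t_end_min"] == t_end_min)]
    df = sel.merge(labels, on="patient_id", how="inner")
    df["label"] = (df["class_label"] == "LBD").astype(int)
    return df


def evaluate_diagnostics(
    results: pd.DataFrame,
    labels: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Full diagnostic-performance report from a fitted results table.

    ``labels`` needs ``patient_id``, ``class_label`` and (optionally)
    ``subgroup`` columns.  Patients with non-positive iLoss are excluded from
    ratio-based analyses and counted in the report.
    """
    config = config or PipelineConfig()
    df = _index_frame(results, labels)
    master = np.random.SeedSequence(config.seed)
    seeds = master.generate_state(8) % (2**31 - 1)

    roc_rows = {}
    index_cols = [c for c in INDEX_ORIENTATIONS if c in df.columns]
    for i, name in enumerate(index_cols):
        sub = df.dropna(subset=[name])
        r = roc_auc(
            sub[name].to_numpy(), sub["label"].to_numpy(),
            positive_high=INDEX_ORIENTATIONS[name],
            n_boot=config.n_boot, seed=int(seeds[0]) + i,
        )
        roc_rows[name] = {
            "auc": r.auc, "ci95": list(r.ci95), "cutoff": r.cutoff,
            "sensitivity": r.sensitivity, "sens_ci95": list(r.sens_ci95),
            "specificity": r.specificity, "spec_ci95": list(r.spec_ci95),
            "n": int(len(sub)),
        }

    excluded_nonpos_iloss = int((df["iLoss"] <= 0).sum())

    # paired bootstrap comparisons vs the early HMR on complete cases
    comparisons = {}
    if "eHMR" in df.columns:
        for j, name in enumerate(n for n in ("iLoss", "ratio", "dHMR", "WR")
                                 if n in df.columns):
            sub = df.dropna(subset=[name, "eHMR"])
            comparisons[f"{name}_vs_eHMR"] = bootstrap_auc_test(
                sub[name].to_numpy(), sub["eHMR"].to_numpy(),
                sub["label"].to_numpy(),
                positive_high_a=INDEX_ORIENTATIONS[name],
                positive_high_b=INDEX_ORIENTATIONS["eHMR"],
                n_boot=config.n_boot, seed=int(seeds[1]) + j,
            )

    # SMOTE balancing in the (iLoss, iUp/iLoss) plane, then repeated SVMs
    ml = df.dropna(subset=["iLoss", "ratio"])
    ml = ml[ml["iLoss"] > 0]
    X = ml[["iLoss", "ratio"]].to_numpy()
    y = ml["label"].to_numpy()
    Xb, yb = smote(X, y, k=config.smote_k, seed=int(seeds[2]))
    classifiers = {}
    for k, kernel in enumerate(config.svm_kernels):
        ev = repeated_svm_evaluation(
            Xb, yb, kernel=kernel, n_runs=config.n_runs,
            train_frac=config.train_frac, seed=int(seeds[3]) + k,
        )
        classifiers[kernel] = {
            "mean_auc": ev.mean_auc, "mean_dor": ev.mean_dor,
            "n_runs": ev.n_runs,
        }
    classifiers["fixed_cutoffs"] = _fixed_cutoff_dor(
        Xb, yb, df, config, seed=int(seeds[4])
    )

    # Dunnett subgroup comparison vs the pRBD-negative PD reference
    subgroups = {}
    if "subgroup" in df.columns:
        for name in ("ratio", "iLoss", "eHMR", "dHMR"):
            if name not in df.columns:
                continue
            groups, names = [], []
            for g in LBD_SUBGROUPS:
                vals = df.loc[df["subgroup"] == g, name].dropna().to_numpy()
                if vals.size >= 2:
                    groups.append(vals)
                    names.append(g)
            if "PD_pRBDneg" in names and len(groups) >= 2:
                ref = names.index("PD_pRBDneg")
                p = dunnett_comparison(groups, reference_index=ref,
                                       seed=int(seeds[5]))
                others = [g for g in names if g != "PD_pRBDneg"]
                means = {g: float(df.loc[df["subgroup"] == g, name].mean())
                         for g in names}
                subgroups[name] = {
                    "adjusted_p": dict(zip(others, p.tolist())),
                    "group_means": means,
                }

    return {
        "provenance": {
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_patients": int(df["patient_id"].nunique()),
        },
        "roc": roc_rows,
        "auc_comparisons_p": comparisons,
        "excluded_nonpositive_iloss": excluded_nonpos_iloss,
        "classifiers": classifiers,
        "subgroups": subgroups,
    }


def _fixed_cutoff_dor(Xb, yb, df, config, seed: int) -> dict:
    """Mean DOR of the fixed two-cutoff rule (iLoss high AND ratio low) over
    repeated test splits of the balanced sample."""
    cut_loss, _, _ = youden_cutoff(
        df.dropna(subset=["iLoss"])["iLoss"].to_numpy(),
        df.dropna(subset=["iLoss"])["label"].to_numpy(), positive_high=True)
    ratio_df = df.dropna(subset=["ratio"])
    cut_ratio, _, _ = youden_cutoff(
        ratio_df["ratio"].to_numpy(), ratio_df["label"].to_numpy(),
        positive_high=False)
    from sklearn.model_selection import train_test_split

    child = np.random.SeedSequence(seed).generate_state(config.n_runs) % (2**31 - 1)
    dors = []
    for i in range(config.n_runs):
        _, X_te, _, y_te = train_test_split(
            Xb, yb, train_size=config.train_frac, stratify=yb,
            random_state=int(child[i]),
        )
        pred = (X_te[:, 0] >= cut_loss) & (X_te[:, 1] <= cut_ratio)
        tp = int(np.sum(pred & (y_te == 1)))
        fp = int(np.sum(pred & (y_te == 0)))
        fn = int(np.sum(~pred & (y_te == 1)))
        tn = int(np.sum(~pred & (y_te == 0)))
        dors.append(diagnostic_odds_ratio(tp, fp, fn, tn))
    return {
        "cutoff_iLoss": float(cut_loss),
        "cutoff_ratio": float(cut_ratio),
        "mean_dor": float(np.mean(dors)),
        "n_runs": config.n_runs,
    }


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    cohort, _ = generate_cohort(config.cohort, out_dir=out_dir, seed=config.seed)
    logger.info("wrote %d patients (%d LBD) to %s", len(cohort),
                int((cohort["class_label"] == "LBD").sum()), out_dir)
    return cohort


def run_fit(config: PipelineConfig, tac_dir: str | Path,
            out_dir: str | Path) -> pd.DataFrame:
    tacs = read_tac_table(Path(tac_dir) / "tacs.csv")
    results = analyze_cohort(
        tacs, config.cohort.corrections, config.end_times_min,
        config.models, config.t_start_min, config.weighting,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "results.csv", index=False)
    return results


def run_evaluate(config: PipelineConfig, results: pd.DataFrame,
                 labels: pd.DataFrame, out_dir: str | Path) -> dict:
    report = evaluate_diagnostics(results, labels, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    pd.DataFrame(report["roc"]).T.to_csv(out_dir / "roc_table.csv")
    return report
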