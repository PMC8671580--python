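# dpskin

Kinetic modelling and diagnostic evaluation for 30-minute **dynamic planar
scintigraphy (DPS)** of myocardial ^123^I-MIBG.

^123^I-MIBG is a radiolabelled norepinephrine analogue taken up by cardiac
sympathetic nerve terminals. Conventional practice acquires two static scans
hours apart and reports the heart-to-mediastinum count ratio (HMR) and the
washout rate (WR) — indices that ignore the tracer's dynamics and force long
waits on patients being evaluated for Lewy body disease (LBD). This package
implements the alternative: a single 30-min dynamic acquisition whose heart
and mediastinal time–activity curves (TACs) are converted into turnover rate
constants by compartment modelling. It is aimed at nuclear-medicine
physicists and methods researchers who want to study, extend, or stress-test
the approach; because clinical DPS data are not publicly available, the
package ships a synthetic-cohort generator with known ground truth so every
stage is verifiable.

## The model

The mediastinal curve (mTAC) is fitted with a three-phase exponential (peak
offset `t0`, constant term) and converted to a plasma parent-tracer input
function with two population-based corrections — the blood-to-plasma ratio
BPR(t) (floored at 0.6 for the first 45 s, haematocrit 40 %) and the plasma
parent fraction PBMC(t) (declining from 1 toward ~30 %):

```
PIF(t) = mTAC_fit(t) · PBMC(t) / BPR(t)
tTAC(t) = hTAC(t) − mTAC_fit(t)
```

The tissue curve follows a one-tissue compartment model,

```
tTAC(t) = [PIF ⊗ iUp·exp(−iLoss·t)](t) + iNs·PIF(t)
```

with `iUp` (min⁻¹) the unidirectional uptake rate into vesicular trapping,
`iLoss` (min⁻¹) the fractional loss (turnover) rate of trapped tracer, and
`iNs` (unitless) the non-specific interstitial fraction (omitted in the
two-parameter variant, 1T2P). Fits are frame-duration-weighted nonlinear
least squares over 1–30 min; model choice uses
`AIC = N·ln(WSSR) + 2p` and `SIC = N·ln(WSSR) + p·ln(N)`. Derived indices
are `iUp/iLoss` (specific distribution) and the pharmacological half-life
`0.693/iLoss`. Estimates are deliberately unconstrained: negative values are
quality flags, tallied as `NegCnt` in the scan-truncation study.

The diagnostics layer evaluates how well each index (iLoss, iUp/iLoss, eHMR,
dHMR, WR) separates LBD from non-LBD: ROC/AUC with bootstrap CIs, Youden
cut-offs, paired bootstrap AUC comparison, SMOTE class balancing, linear and
RBF SVMs over repeated 70/30 splits with diagnostic odds ratios, and Dunnett
many-to-one subgroup comparison.

## Worked example

```python
import dpskin as dk

cfg = dk.CohortConfig()
for group in ("PD_pRBDpos", "nonLBD"):          # one LBD patient, one control
    rec = dk.sample_patient(cfg, group, seed=23)
    htac, mtac = dk.simulate_scan(rec)           # decay-corrected ROI curves
    mfit = dk.fit_mtac(mtac, t_end_min=30)       # tri-exponential blood proxy
    pif = dk.ParametricPIF(mfit, cfg.corrections)
    ttac = dk.build_ttac(htac, mfit)
    fit = dk.fit_kinetics(ttac, pif, model="1T3P", t_start_min=1, t_end_min=30)
    idx = dk.derive_indices(fit)
    print(f"{group:10s} iUp={fit.iUp:.4f} iLoss={fit.iLoss:.4f} "
          f"(true {rec.true_iLoss:.4f}) iUp/iLoss={idx.ratio:.2f} "
          f"t1/2={idx.half_life_min:.1f} min eHMR={dk.hmr(htac, mtac):.2f}")
```

prints

```
PD_pRBDpos iUp=0.0853 iLoss=0.0722 (true 0.0722) iUp/iLoss=1.18 t1/2=9.6 min eHMR=3.20
nonLBD     iUp=0.1479 iLoss=0.0413 (true 0.0413) iUp/iLoss=3.58 t1/2=16.8 min eHMR=5.69
```

The diseased patient shows the expected signature: faster turnover (higher
`iLoss`, shorter half-life) and a smaller specific distribution `iUp/iLoss`,
both recovered to within a percent of the simulated ground truth at this
noise level.

The same chain is available from the shell:

```bash
dpskin report --out runs/demo --seed 1        # simulate -> fit -> evaluate
dpskin simulate --out runs/cohort --seed 1
dpskin fit --tac-dir runs/cohort --out runs/cohort
dpskin evaluate --results runs/cohort/results.csv \
                --labels runs/cohort/cohort.csv --out runs/cohort
```

`report.json` contains the ROC table (AUC, CI, Youden cut-off, sensitivity,
specificity per index), bootstrap AUC comparisons against the early HMR, the
SMOTE-balanced SVM summaries, Dunnett subgroup p-values, and a provenance
block (package version, config digest, master seed).

## Layout

| module | contents |
| --- | --- |
| `dpskin.tac` | frame schedules, TACs, decay correction, CSV I/O |
| `dpskin.input_function` | tri-exponential mTAC fit, BPR/PBMC corrections, PIF, tissue curve |
| `dpskin.kinetics` | forward model, `OneTissueModel` estimator, AIC/SIC, truncation study |
| `dpskin.static_indices` | eHMR, dHMR, WR, linear and monomolecular regressions |
| `dpskin.diagnostics` | ROC/Youden, bootstrap AUC test, SMOTE, repeated SVMs, DOR, Dunnett |
| `dpskin.cohort` | synthetic patients: class-conditional parameters, scan simulation |
| `dpskin.pipeline`, `dpskin.cli` | orchestration, reports, `dpskin` command |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
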