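# Methods

This note records the modelling assumptions, numerical choices and
limitations of `dpskin`, in the spirit of the model documentation shipped
with packages like statsmodels or msprime. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Acquisition model and conventions

The standard schedule is a 30-min dynamic sequence started at bolus
injection (30 × 2 s, 40 × 6 s, 75 × 20 s — 145 frames, 1800 s) plus two
3 × 300 s static blocks at 90 and 180 min; the full grid ends at 195 min so
the delayed HMR window (190–195 min) is covered. Frames are half-open
`[start, start+duration)` with times in seconds from injection. Curve values
are mean counts/pixel/second (rates); whether the acquisition software
exports rates or per-frame counts is not standardised, and the rate
convention is this package's choice — it makes 2 s and 300 s frames directly
comparable. All analysis curves are decay-corrected to injection time with
the ^123^I half-life (13.2235 h, configurable). Measured curves are never
interpolated across the gaps between scan blocks; only fitted/parametric
curves are evaluated there.

## Input function

The mediastinal curve serves as a whole-blood surrogate. It is fitted from
its observed peak frame with
`m(t) = Σᵢ Aᵢ·exp(−λᵢ·(t−t0)) + C` (three phases, all amplitudes/rates and
the constant non-negative, `t0` co-estimated within one frame of the
observed peak midpoint), weighted by frame duration. Pre-peak extrapolation
holds the peak value. Multi-start: ten log-spaced scalings of the base rates
(1.0, 0.1, 0.01 min⁻¹), amplitudes screened by non-negative least squares,
the three best starts polished by bounded least squares. A component with no
variation over the fit window is folded into the constant term so degenerate
inputs (e.g. a flat curve) return the canonical `C = value, A = 0` form.

Plasma corrections are parametric stand-ins for population curves
originally derived from blood sampling and HPLC, which are not reproduced
here; **their time constants are assumptions**, prominently configurable:

* BPR(t) = 0.6 for t ≤ 45 s (haematocrit 40 %), then rising as
  `0.6 + (plateau − 0.6)(1 − e^(−k(t−45 s)))`, defaults plateau 1.0,
  k 0.05 min⁻¹ — continuous and monotone.
* PBMC(t) = `0.30 + 0.70·e^(−k·t)`, default k 0.03 min⁻¹ — parent fraction
  starts at 1 and declines toward the ~30 % plateau.

`PIF = mTAC_fit · PBMC/BPR`; the tissue curve is `hTAC − mTAC_fit`. No
spillover or partial-volume modelling beyond this subtraction.

## Kinetic fit

The forward model is evaluated on a uniform 1-s grid spanning the fit
window. The exponential-kernel convolution uses the exact constant-segment
propagator per grid interval (`c_k = c_{k−1}e^(−iLoss·Δ) + p̄_k(1−e^(−iLoss·Δ))/iLoss`
with `p̄_k` the input at the interval midpoint), so piecewise-constant
inputs are handled exactly and smooth inputs at second order. Model values
are frame averages by default (frames span 2–300 s; midpoint sampling is an
option for speed).

Fitting minimises `Σ wⱼ(yⱼ − modelⱼ)²` with `wⱼ ∝` frame duration (the
approximate-Poisson alternative `duration/value` is a config option). The
fit starts at 1 min — the interstitial term assumes sub-minute equilibration
of the extracellular space with plasma — and ends at the truncation time
under study (default 30 min). Because the model is linear in `(iUp, iNs)` at
fixed `iLoss`, those coefficients are profiled out by a weighted linear
solve and the single nonlinear parameter is minimised over a deterministic
coarse grid (−0.1…0.6 min⁻¹, widened automatically at the edges) followed by
bounded scalar minimisation (xatol 1e−10). Estimates are **unconstrained**;
negative values are reported and tallied (`NegCnt`), not clamped. A fit with
WSSR below 1e−12 is flagged degenerate and the WSSR is floored at 1e−12
before `ln(WSSR)` enters AIC/SIC. `N` in the criteria counts fitted frames
only. The half-life uses the literal coefficient 0.693 as conventionally
printed, not ln 2.

## Static indices

HMRs are duration-weighted window means (10–15 and 190–195 min) of
heart over mediastinum counts/pixel. WR compares mediastinum-subtracted,
decay-corrected uptake between the two windows; since both differences are
rescaled by a common factor per window, the choice of decay-correction
reference time cancels algebraically and curves corrected to injection time
are used directly. WR is flagged undefined when early uptake is
non-positive. The iLoss–WR relation is modelled with the
one-phase-association form `y = Y0 + (plateau − Y0)(1 − e^(−rate·x))` so the
origin and asymptote are directly testable.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
the imaging physics. Default cohort: 166 patients — 105 LBD (35 PD with
probable RBD, 61 PD without, 9 DLB) and 61 non-LBD. Per group, `iLoss` and
the ratio `iUp/iLoss` are log-normal with moment-matched mean/SD
(`iUp = ratio·iLoss`), and `iNs` is a zero-truncated normal
(mean 0.21, SD 0.11). The three disease subgroups use the published
subgroup statistics as calibration anchors
(iLoss 0.0647/0.0170, 0.0557/0.0129, 0.0683/0.0247 min⁻¹; ratio 1.17/0.47,
2.30/1.67, 1.09/0.68). No non-LBD distribution is published — only
cut-offs — so the control group is this package's calibration choice:
iLoss log-normal mean 0.038 min⁻¹ (SD 0.007), anchored to the reported
normal loss rate (< 0.035 min⁻¹) of a reference catecholamine PET tracer,
and ratio mean 3.5 (SD 1.0). `iUp` and `iLoss` are independent within a
patient by default; a positive-correlation option exists but its magnitude
is not printed anywhere, so it is off.

Each patient's mediastinal template is the bolus-like tri-exponential
(A = 40, 8, 2 cps/pixel; λ = 2.0, 0.15, 0.01 min⁻¹; C = 0.8; t0 = 0.5 min)
with 10 % log-normal jitter per parameter. The simulator runs the forward
pipeline: mediastinum sampled at frame midpoints, tissue as the
frame-averaged forward model driven by the corrected template, heart =
tissue + mediastinum. Counting noise is zero-mean Gaussian with
`σ = noise_level·√(rate/duration)`; `noise_level = 0.05` equals exact
Poisson statistics on a per-pixel rate averaged over ~400 ROI pixels. An
exact-Poisson mode exists. Negative mediastinal samples are clipped at zero
and counted.

What passing tests on this cohort do **not** show: performance on real
patients. The simulator omits scatter, attenuation, ROI mis-placement,
motion, inter-patient variation in the correction curves, and any
iUp–iLoss correlation; HMR magnitudes are therefore on the simulator's own
scale rather than the clinical ~1.2–2.5 range, and diagnostic AUCs reflect
the configured class separation, not clinical accuracy.

## Diagnostics

AUC is the Mann–Whitney probability with half credit for ties; CIs use a
stratified bootstrap (2000 replicates). Youden cut-offs come from the
observed score set, ties broken deterministically toward the candidate
nearest the median score. Index polarity is explicit: high iLoss and WR
indicate disease; low iUp/iLoss, eHMR and dHMR do. The paired AUC
comparison refers the observed difference to its stratified-bootstrap
standard deviation (normal two-sided p). SMOTE is implemented in-package
(interpolation to one of k = 5 nearest minority neighbours at a uniform
fraction); balancing is done once up front before the repeated splits, with
a per-fold mode available. SVMs use C = 1, RBF bandwidth by the inverse
feature-variance heuristic, features standardised on the training fold
only; splits are stratified (a stabilising deviation from plain random
splitting, default on). DOR adds 0.5 to every confusion cell when any cell
is zero. The fixed two-cutoff classifier declares disease when iLoss ≥ its
cut-off **and** iUp/iLoss ≤ its cut-off (the "territory" rule; the
published rule is not printed). Dunnett's many-to-one test is delegated to
`scipy.stats.dunnett`. All stochastic procedures derive their seeds from a
single master seed by counter, so reports are bit-reproducible.

Patients with non-positive fitted `iLoss` are excluded from ratio-based ROC
analyses and counted in the report, mirroring the `NegCnt` bookkeeping.

## Problem sizes in the shipped checks

The test suite exercises: the 166-patient default cohort at the default
noise level for the recovery-under-noise and class-separation checks; a
50-patient cohort for the truncation/model-selection behaviour (5 vs 30 min
end times); and 10,000-draw samples for generator calibration. These sizes
were chosen to make the checks statistically meaningful at desk scale while
keeping a full test run to a few minutes.

## Known limitations

* BPR/PBMC shapes are assumptions; subject-specific haematocrit and
  metabolite kinetics are out of scope.
* Whether the published mediastinal fit constrains amplitudes non-negative
  is unknown; this package does (and documents the unconstrained kinetic
  fit separately).
* `iLoss ≈ 0` makes the ratio and half-life ill-defined; they are flagged
  rather than imputed.
* The 1T3P/1T2P family ignores a distinct free-cytosol compartment; `iLoss`
  is a lumped turnover surrogate.
* Truncation columns at 105/195 min rely on the parametric input function
  bridging the scan gaps.
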