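# Methods

This note documents the models implemented in `piperpbpk`, the default
parameter values and why they were chosen, the numerical choices, and the
known limitations — in particular where this open reimplementation is
expected to differ from proprietary simulation platforms.

## Intrinsic clearance from substrate depletion

Substrate depletion in human liver microsomes is modeled as first-order:
remaining% = 100·e^(−kt). The decay rate is estimated by ordinary least
squares on ln(% remaining) vs time (minutes), including the t = 0 anchor;
triplicate incubations are averaged per time point before fitting, since
condition-level summaries (one SD per condition) imply condition-level
fits. The fitted coefficient is negated and floored at zero, so a flat or
rising time course yields CLint = 0 rather than a negative clearance.
CLint = 1000·k/P (µL/min/mg protein ≡ mL/min/g protein). Condition-level
values are pooled by *unweighted* arithmetic mean — the only combination
consistent with the published pooled value of 24.2 µL/min/mg from
{33.2, 12.9, 34.0, 10.6, 10.3, 44.2} — variance weighting is deliberately
not applied.

## Physiology defaults

Standard 70-kg adult values: hematocrit 0.45, hepatic blood flow 90 L/h,
liver 1650 g, MPPGL 40 mg/g, GFR 7.2 L/h, blood volume 0.0771 L/kg,
small-intestinal radius 1.75 cm, villous blood flow 18 L/h, plasma pH 7.4,
tissue intracellular pH 7.0, blood-cell pH 7.22. CYP3A4 degradation rates
default to 0.0193 h⁻¹ in liver and 0.03 h⁻¹ in gut (turnover half-lives
≈ 36 h and 23 h, the values most widely used in interaction modeling).
All are overridable on the `Physiology` record.

## Tissue partitioning and Vss (mechanistic method 2)

For a monoprotic base, the unbound tissue:plasma partition coefficient is

    Kpu = f_EW + (X/Y)·f_IW + KaAP·AP·10^(pKa−pH_IW)/Y
          + (P·f_NL + (0.3P + 0.7)·f_NP)/Y

with X = 1 + 10^(pKa−pH_IW), Y = 1 + 10^(pKa−pH_plasma), P = 10^logP
(vegetable-oil scale 10^(1.115·logP−1.35) for adipose). KaAP is
back-calculated from the blood-cell coefficient implied by the measured
B/P and fu (Kpu_BC = (B/P−(1−Hct))/(Hct·fu)), using the same equation
solved for KaAP; the tiny blood-cell neutral-lipid terms are retained for
exact internal consistency, which makes the blood-cell round trip close to
machine precision. Piperine's pKa of 12.22 makes it effectively fully
ionized at physiological pH; the general base equations are used without a
special case. Plasma-protein-binding tissue terms used for acids/neutrals
in the same framework are present but inactive for strong bases.

    Vss = V_plasma + Σ_t V_t·Kpu_t·fu_plasma   (plasma-referenced)

with blood cells included as a tissue via hematocrit and no empirical Kp
scalar.

**Tissue table provenance.** The bundled table combines the published
composition dataset of the partitioning method's authors (fractional
water/lipid values and acidic-phospholipid concentrations, originally
rat-derived but routinely applied to human prediction, including by the
method's authors) with ICRP-style human fractional tissue volumes.
Proprietary platforms carry their own human composition tables. With the
bundled data the piperine prediction is 0.583 L/kg versus the
platform-predicted 0.826 L/kg (fold-error 0.71 — within the two-fold
criterion used for PK validation, but a real provenance gap). Because the
dominant term is the acidic-phospholipid association, whose scale is set
by the ratio AP_tissue/AP_blood-cells, modest differences in composition
data move all Kpu values together; no attempt was made to calibrate the
table toward the platform value. The PK simulations therefore use the
published input Vss (0.826 L/kg) exactly as the original analysis did,
while `vss_method2` reports the mechanistic prediction for transparency.

## Oral PBPK engine

State variables per compound: gut-lumen amount, systemic amount, and
three cumulative bookkeeping amounts (gut-wall metabolized, hepatic
first-pass extracted, systemically eliminated); everything in mg.

- **Absorption** is first order with fa = 1 and ka = 2·Peff/R
  (5.13×10⁻⁴ cm/s → 2.11 h⁻¹ for piperine). This is the principal
  structural simplification relative to a multi-segment
  dissolution/absorption (ADAM-type) model: the capsule's
  dissolution-limited kinetics (solubility 0.004 mg/mL) are not modeled.
  The piperine PK validation still falls within the two-fold band, which
  is the criterion the original analysis itself applies; consequences for
  the interaction predictions are discussed under Limitations.
- **Enterocyte, quasi-steady-state.** The enterocyte washout rate
  Qgut/V_ent ≈ 15 h⁻¹ greatly exceeds ka ≈ 2 h⁻¹, so the enterocyte is
  treated as instantaneously equilibrated: absorbed flux is split by
  Fg(t) = Qgut/(Qgut + fu_gut·CLint,gut,u·E_gut(t)), and the enterocyte
  concentration used as the gut TDI driver is Fg·ka·A_lumen/Qgut. This
  makes the Bateman limit exact when extraction is disabled and the mass
  balance closed-form.
- **Liver, quasi-steady-state.** Under the perfusion-limited well-stirred
  assumption the liver is an instantaneous extractor: first-pass input is
  multiplied by F_h(t) and systemic blood is cleared at CLh(t), both
  recomputed each step from active-enzyme-scaled CLint. Piperine's renal
  clearance defaults to 0 (no urinary-excretion datum); the filtration
  pathway (fu_b·GFR) exists for victims and sensitivity work.
- **Dosing** events are exact state discontinuities; the integrator
  restarts at each dose time. Output lands on a fixed grid (default
  0.05 h); grid points at a dose time report the pre-dose state.
- **Units**: concentrations reported as plasma ng/mL via B/P; inhibitor
  drivers converted to µM via 1000/MW.
- **NCA**: Cmax/Tmax by grid maximum, AUC by linear trapezoid. Single-dose
  piperine metrics use 0–24 h; multiple-dose Cmax is read on day 7
  (144–168 h); the multiple-dose AUC window is configurable because the
  clinical sampling window behind the observed value is not stated.

## Interaction simulation

Perpetrator PK, both enzyme sites, and victim PK are integrated jointly
(12 states). Default scenario: piperine 20 mg/day for 7 days; victim
single dose simultaneous with the 7th piperine dose (the study design
gives no finer co-timing); victim exposure read over a 72-h post-dose
window, long enough to cover ≥ 75% of AUC for the slowest victim while
keeping the comparison window identical in both arms. Kapp is
unbound-corrected by fu_mic (0.863); the measured microsomal CLint is
likewise divided by fu_mic before IVIVE scaling (standard practice; a
switch disables it, and both variants stay within the two-fold PK band).
Reversible (competitive) inhibition by piperine is omitted: the input set
contains only inactivation constants. Piperine auto-inhibition of its own
clearance is off by default (its clearance is not assigned to CYP3A4),
available as a flag; the observed day-7/day-1 Cmax ratio (≈ 2.05) exceeds
linear accumulation, hinting that this assumption loses some real
nonlinearity.

**Victim parameter fixture.** The platform's built-in victim files are
unpublished, so `data/victims.tsv` is a documented, literature-informed
stand-in: one-compartment oral PK per victim (dose from the studied
scenario; fu, B/P, Vss from standard clinical-pharmacology references;
hepatic CLint,u back-calculated from reported systemic clearance via the
well-stirred model; fm_CYP3A4 from published fraction-metabolized
analyses; gut CLint set to reproduce reported intestinal availability
through the Qgut model). Quantitative AUC ratios for victims other than
midazolam should be read as ordering/threshold indicators, not point
predictions.

## Virtual population

Only CYP3A4 expression varies: log-normal multipliers with median 1 and
σ = √ln(1+CV²) applied to abundance (CV 41%, scaling every CYP3A4-mediated
clearance term) and to kdeg at both sites (CV 68%). Demographic covariates
are out of scope — no covariate model is described for the study
population. SEM is computed on the natural scale across all subjects.
Per-subject seeds derive from a counter-based stream
(`default_rng([master_seed, subject_index])`), so enlarging a design never
reshuffles existing subjects; the default master seed is 20241011.

## Numerical choices

LSODA with rtol 1e-8 and atol 1e-12 mg throughout; inhibitor drivers are
clamped at zero against sub-tolerance negative excursions. Dose events are
handled by piecewise integration, never by stiff forcing. Degenerate
inputs fail loudly (`InvalidInputError`) rather than silently: empty
pools, non-positive remaining percentages, missing tissues (named in the
error), fractions outside (0, 1], victims without fm_CYP3A4.

## What the synthetic data does and does not emulate

The depletion generator reproduces the assay design (sampling at 0, 7,
17, 30, 60 min) with multiplicative log-normal noise, zero-anchored at
t = 0 — it does not emulate LLOQ censoring or fluorescence QC. The
"observed profile" generator produces clinical-like sparse samples from a
perturbed model — closing the loop exactly at zero noise — so validation
tests demonstrate internal consistency and estimator behavior, not
agreement with any new clinical dataset. Passing them shows the pipeline
recovers known ground truth under its own assumptions.

## Problem sizes

Default runs are sized for interactive use: 7-day piperine simulation
≈ 0.1 s; one victim co-simulation (two 9-day joint integrations) ≈ 0.2 s;
the full ten-victim table ≈ 1 s; the test suite, including a 200-replicate
depletion recovery study and a 10⁴-subject sampler check, a few seconds.

## Known limitations

1. **Absorption structure.** First-order absorption with fa = 1 makes
   piperine's gut exposure brief (enterocyte residence ~minutes–hours),
   whereas dissolution-limited release would sustain it. The
   time-averaged gut inactivation driver is bounded by
   fu_gut·Dose/(Qgut·MW) per day regardless of ka, so gut CYP3A4
   depletion is modest here (E_gut ≈ 0.99 at day 7) and the predicted
   interaction magnitudes for strongly gut-extracted victims
   (simvastatin) sit well below those reported with full platform
   models (AUC ratio 1.13 vs 1.59). The hepatic site behaves similarly
   (E_liver ≈ 0.89). The *ordering* of victims is robust to this; the
   absolute ratios are conservative.
2. **Tissue composition provenance** (see above): mechanistic Vss is
   ~30% below the platform value; simulations use the input Vss.
3. One-compartment victims without parent–metabolite kinetics
   (simvastatin is modeled as the lactone probe), no transporters, no
   CYP3A5, no induction, no enterohepatic recirculation.
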