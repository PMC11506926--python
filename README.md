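# piperpbpk

An open, tested pipeline for predicting food–drug interactions between
dietary **piperine** (the pungent alkaloid of black pepper) and drugs
cleared by **CYP3A4**. Piperine is a mechanism-based (time-dependent)
inactivator of CYP3A4: culinary-scale intake (≈ 20 mg/day) can slowly
deplete active enzyme in the gut wall and liver and raise the exposure of
co-administered CYP3A4 substrates. The package builds a mechanistic oral
PBPK model of piperine from in vitro data, validates it against observed
clinical pharmacokinetics by the standard two-fold fold-error criterion,
and co-simulates ten victim drugs to rank their interaction risk.

Intended users: DMPK / clinical-pharmacology modelers who want an
inspectable, scriptable alternative to closed commercial platforms for
this class of perpetrator-victim problem.

## What it computes

**Intrinsic clearance from substrate depletion.** ln(% remaining) vs time
in human liver microsomes gives a first-order slope *k*, and

    CLint (µL/min/mg) = 1000 · k / P

with *P* the microsomal protein concentration (mg/mL). Condition-level
estimates are pooled by unweighted mean into the model input
(24.2 µL/min/mg for piperine).

**IVIVE and the well-stirred liver.** Whole-liver CLint,u =
CLint · MPPGL · liver weight / fu_mic, then
CLh = Qh·fu_b·CLint,u / (Qh + fu_b·CLint,u), with fu_b = fu_p/(B/P).

**Mechanistic volume of distribution** (tissue-composition "method 2"):
tissue water is split into intra-/extra-cellular fractions, the ionized
base associates with tissue acidic phospholipids (KaAP back-calculated
from blood-cell partitioning), and Vss = V_p + Σ V_t·Kpu_t·fu_p.

**Oral PBPK engine.** First-order absorption (ka = 2·Peff/R), a
quasi-steady-state enterocyte with the hybrid Qgut flow governing gut-wall
first pass Fg = Qgut/(Qgut + fu_gut·CLint,gut,u), an instantaneous
well-stirred hepatic first pass, and a one-compartment systemic space
sized by Vss.

**Enzyme turnover and interaction.** Active CYP3A4 at each site follows
dE/dt = kdeg(1−E) − λ·E with λ = kinact·I_u/(Kapp,u + I_u); the hepatic
driver is the unbound liver-inflow blood concentration, the gut driver the
unbound enterocyte concentration. Victim hepatic CLint scales with
fm_CYP3A4·E_liver + (1−fm); gut CLint with E_gut. AUC/Cmax ratios
(with/without 7 days of piperine 20 mg/day) quantify the interaction; a
ratio ≥ 1.25 is the regulatory trigger for a clinical DDI study.

**Virtual trials.** Log-normal between-subject variability in CYP3A4
abundance (CV 41%) and turnover (CV 68%), 10 trials × 10 subjects,
summarized as geometric mean ± SEM and 5th/95th percentiles.

## Worked example

```bash
$ piperpbpk ivive
whole_liver_clint_l_h=95.832
clint_unbound_l_h=111.046
clh_l_h=4.99378
eh=0.0554864
fh=0.944514

$ piperpbpk vss | tail -2
ka_ap=6.62454
vss_l_kg=0.582789

$ piperpbpk simulate --days 1
cmax_ng_ml=296.552
tmax_h=1.75
auc_ng_ml_h=4334.08

$ piperpbpk ddi midazolam
...
auc_ratio=1.1258
cmax_ratio=1.05358
e_liver_at_victim_dose=0.891843
e_gut_at_victim_dose=0.991542
```

Reading: piperine's pooled microsomal CLint scales to a hepatic blood
clearance of ~5 L/h (extraction 5.5%, so the liver lets 94% of an oral
dose through). A 20 mg capsule peaks at ~297 ng/mL (observed 290 ± 15;
fold-error 1.0) with AUC₀₋₂₄ 4334 ng/mL·h (observed 5642 ± 338;
fold-error 0.8) — inside the two-fold acceptance band, as is the day-7
Cmax under repeated dosing (410 vs 595 ng/mL, fold-error 0.7). Seven days
of piperine leave ~89% of hepatic and ~99% of gut CYP3A4 active, which
raises midazolam exposure by ~13% (clinical corroboration for a similar
regimen: +21%). `piperpbpk run` prints the full ten-victim table sorted by
AUC ratio — simvastatin ranks highest and carbamazepine lowest, matching
the qualitative ordering expected from their CYP3A4 dependence.

The mechanistic Vss (0.583 L/kg) is reported by `vss` for comparison with
the platform-predicted 0.826 L/kg input; the bundled public
tissue-composition dataset is known to differ from proprietary ones, and
the simulations use the input value (see `docs/methods.md`).

Other subcommands: `clint` (fit depletion tables), `trial` (population
runs), `validate` (two-fold report), `synth` (generate synthetic inputs),
`run` (whole study).

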