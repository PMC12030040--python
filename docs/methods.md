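# Methods

## Model structure

The engine integrates a minimal PBPK system per compound and subject:

* gut solid → gut dissolved, at a Weibull dissolution hazard (or a
  tabulated cumulative dissolution curve, interpolated monotonically);
* gut dissolved → portal absorption, first-order ka; a fraction fa·fg
  reaches the portal inlet, of which Fh = 1 − Eh escapes hepatic first
  pass (Eh from the well-stirred model, re-evaluated continuously so that
  enzyme inhibition changes first pass as well as systemic clearance);
* systemic compartment (volume V_sys = Vss/(1 + kin/kout) × body weight)
  exchanging with a single adjusting compartment at first-order kin/kout;
* elimination from the systemic compartment: hepatic plasma clearance
  (well-stirred, per-enzyme intrinsic clearances summed) plus renal plasma
  clearance (filtration fu,p·GFR plus per-transporter secretion, scaled by
  1 − f_reab).

Amounts are tracked in mg per compartment with cumulative elimination
booked per pathway, so administered dose = remaining + eliminated holds to
solver tolerance at every output time (asserted < 1e-6 relative in tests;
in practice ~1e-12). Doses are injected by integration restarts at dose
times; no impulse smoothing. Solver: LSODA via `scipy.integrate.solve_ivp`,
rtol 1e-8, atol 1e-10 mg, output grid 0.1 h by default (0.25 h in
population loops — the solver's internal steps are adaptive, the grid only
controls reporting).

Internal unit convention: concentrations µM (µg/mL at the reporting
surface), volumes L, time h, clearances L/h. All conversions happen at the
I/O boundary; mass↔molar conversion uses C[µM] = C[µg/mL]/MW × 1000.

## Reference physiology

A deterministic 70-kg healthy adult (versioned data file): hepatic blood
flow 90 L/h, GFR 7.2 L/h (120 mL/min), liver 1650 g, MPPGL 40 mg/g,
hematocrit 0.45, plasma volume 0.0436 L/kg. These are standard literature
values; they replace the proprietary population database of commercial
platforms and anchor every packaged calibration. Between-subject
variability is log-normal with geometric median at the reference value,
default CV 30% on enzyme activity, transporter activity and Vss (the
clearance- and volume-side multipliers); sex is Bernoulli(proportion
female), age uniform in the design range. Zero CV reproduces the reference
exactly, and the same seed reproduces the same population bit-for-bit.

## The cabotegravir model and its calibrations

Measured inputs: MW 405.4 g/mol, logP 1.58, monoprotic acid pKa 7.71,
B/P 0.54, fu,p 0.006, Papp 25.6×10⁻⁶ cm/s, SAC kin/kout 0.03/0.07 1/h,
recombinant UGT1A1/UGT1A9 CLint 4.5/2.2 µL/min/mg with fu,mic 0.5, OAT1/
OAT3 Ki 0.405/0.205 µM, UGT1A9 Ki 23 µM. A UGT1A1 Ki reported only as
"> 50 µM" is encoded as no UGT1A1 inhibition. Ki values follow the
competitive convention Ki = IC50/2 (substrate ≪ Km).

Four constants are package calibrations, fixed once against clinical
anchors and never re-fit at run time ("middle-out"):

1. **ISEFs and unassigned hepatic pathway.** Recombinant-enzyme CLint
   values need inter-system scaling factors that were never published.
   ISEF(UGT1A1) = 0.3863 and ISEF(UGT1A9) = 0.4687, plus an unassigned
   hepatic pathway (CLint 0.3113 µL/min/mg, fu,mic 1, ISEF 1), reproduce
   simultaneously the observed oral clearance CL/F ≈ 0.14 L/h and the
   reported pathway fractions fm(UGT1A1) = 0.59, fm(UGT1A9) = 0.35. The
   ~5% unassigned share plus ~0.7% renal make up the remainder the
   reported fm values leave unexplained.
2. **Renal clearance.** Direct mode, 0.001 L/h — consistent with < 1% of
   dose excreted unchanged; no mechanism is claimed.
3. **Dissolution and ka.** The measured tablet dissolution profile is not
   published; the packaged file uses a Weibull curve (scale 0.4 h, shape
   1.0) with ka = 0.1 × Papp[10⁻⁶ cm/s] = 2.56 1/h (a one-point
   high-permeability calibration), placing the simulated single-dose Tmax
   at 2.3 h, inside the observed 2–3 h window. fa = fg = 1 (high
   permeability, no intestinal UGT metabolism modelled — a documented
   simplification).
4. **Albumin accessibility** (distribution, below).

With these, the model yields Vss 0.120 L/kg, Tmax 2.3 h, t½ 45.2 h,
CL/F 0.1400 L/h on the reference subject.

## Distribution (Vss) method

Tissue Kp values follow the Rodgers–Rowland tissue-composition equations
for monoprotic acids, neutrals and weak bases: extracellular/intracellular
water terms with Henderson–Hasselbalch ionisation at plasma pH 7.4 and
intracellular pH 7.0, neutral lipid/phospholipid partitioning from logP
(vegetable-oil logD for adipose), and an albumin-type association constant
recovered from fu,p. Strong bases (pKa ≥ 7), which require the acidic-
phospholipid mechanism, are not implemented. Vss = V_plasma + Σ Kp_t·V_t;
the Kp scalar multiplies tissue terms only (the plasma term is fixed), and
drug is excluded from blood cells when B/P < 1 − hematocrit.

The packaged tissue table carries one calibration constant: an
interstitial **albumin accessibility of 0.708** applied to the tissue:
plasma albumin ratios. Interstitial albumin concentrations are only a
fraction of plasma levels, and published tissue albumin-ratio sets are
known to overstate effective binding for very highly bound acids; the
factor was fixed once so the monoprotic-acid prediction with the reported
Kp scalar 1.5 reproduces the reference compound's reported 0.12 L/kg, and
is versioned with the table. Sensitivity of the method's structure (scalar
homogeneity, water-limit behaviour for neutral unbound compounds, the
Vss assembly identity) is tested independently of this constant.

## DDI conventions

* Driving concentrations: unbound hepatic inlet
  I_u = fu,p·C_p + fu,b·(absorption flux/Q_h) for hepatic enzymes; unbound
  systemic plasma for renal basolateral transporters. This follows
  standard mechanistic-static practice.
* Induction is a steady-state multiplier 1 + Ind_max·I/(IndC50 + I)
  evaluated at the perpetrator's average unbound systemic concentration
  over its final dosing interval; enzyme-turnover dynamics are out of
  scope (the relevant clinical scenario uses chronic pre-dosing).
* Coupling is one-way: the perpetrator is simulated first and its dense
  profile drives time-varying multipliers on the victim's pathway
  clearances. Paired arms (with/without perpetrator) share the subject,
  regimen and grid, so ratios are within-subject.
* The mechanistic static equation AUCR = 1/Σ f_p·δ_p over pathway
  fractions is the analytic cross-check: a perpetrator clamped at constant
  exposure reproduces it within 1%, and infinitely potent inhibition
  approaches the saturation bound 1/(1 − Σ fm_affected).

## Trial designs and statistics

The perpetrator-DDI design mirrors the clinical template: perpetrator
30 mg once daily for 14 days, single-dose victim co-administered 2 h after
the day-10 dose (by then the perpetrator is at ≥ 95% of steady state, and
the long half-life makes the ratio insensitive to the ±2 h stagger — the
tests verify < 2% movement). Trials default to 10 × 10 subjects; per-trial
seeds derive deterministically from the master seed via
`numpy.random.SeedSequence.spawn`.

Ratios are summarised on the log scale: geometric means, empirical 5th–95th
percentiles (linear interpolation), and a t-based 90% CI of trial means.
The TOST compares the mean of simulated trial means against a published
ratio with two one-sided limits m ∓ t_{0.95,n−1}·s/√n on the log scale,
passing iff both fall within [published/1.3, published×1.3]; whether the
original analysis used t- or z-limits and trial- or subject-level variance
is unstated, so the t/trial-level convention is flagged in every report.
Both the 1.3-fold and the 80–125% windows are closed intervals. Under the
boundary null the TOST's type-I error is ≈ 5%, and percentile containment
covers ≈ 90% under the exchangeable null (both verified by Monte Carlo in
the suite).

Steady state is declared at the first dosing interval whose AUCτ differs
from the previous one by < 1% (configurable). Note this is stricter than
the clinical "7–8 days" convention for a 45-h half-life drug: the 1% rule
lands on day 11, while the ~95%-of-steady-state convention (rel_tol 0.05)
lands on day 7.

NCA metrics: trapezoidal AUC with Clast/λz tail, λz by log-linear
regression over the trailing 25% of the simulated span (≥ 4 points,
configurable), CL/F = dose/AUC0–inf; profiles spanning < 5 terminal
half-lives are flagged as not well characterised.

## Synthetic fixtures and what they do (not) show

Fixtures are named for their roles (`oat3_victim`, `ugt_inhibitor`, ...),
not for real drugs: the literature parameter sets behind the original
substrate/inhibitor panel are proprietary or unpublished, so no fixture
claims to reproduce a specific clinical interaction. A victim fixture's
headline numbers (total clearance, fe, secretion split, hepatic fm map)
are hit exactly on the reference subject by inverting the IVIVE equations;
construction is deterministic for a given spec. Observed datasets are
simulated truth sampled at a clinical-style schedule with multiplicative
log-normal noise. Passing fixture-based suites therefore demonstrates the
*machinery* — clearance bookkeeping, inhibition propagation, statistics —
under controlled conditions; it does not validate predictions for any real
comedication, and real victims with transporter-mediated hepatic uptake,
nonlinear binding or gut-wall metabolism are outside the model family.

Parameter recovery (`fit_distribution_rates`) refits SAC kin/kout and ka
to a dataset by least squares on log-concentrations; on noiseless
synthetic data the generating values are recovered to ≪ 1%. The numeric
jacobian uses a relative step of 1e-4 with solver tolerances tightened to
1e-10/1e-12 — finite differences at the default step sit below the
adaptive solver's noise floor and stall the optimiser.

## Numerical and design choices

* Dissolution hazards with non-unit Weibull shape (and tabulated curves)
  are evaluated against time since the most recent dose; with multiple
  overlapping doses this is an approximation (exact for shape 1, the
  packaged default).
* The SAC volume split v_sac/v_sys = kin/kout preserves total Vss while
  kin/kout control distribution kinetics; kin = 0 collapses to one
  compartment (used by the analytic-oracle tests).
* fe-decomposed renal clearance: CLr = fe/(1−fe)·CLh,p (fe defined against
  total plasma clearance); secretion = CLr/(1−f_reab) − fu,p·GFR, with a
  configuration error if transporter fractions are supplied but filtration
  already exhausts CLr.
* Sensitivity sweeps run on the deterministic reference subject (the
  reported sweep outputs are means); the fu,p sweep propagates into every
  fu-dependent term (clearance and predicted Vss), and fu is clamped at 1
  with a recorded warning.
* Blood→plasma clearance conversion is explicit: CL_p = CL_b × B/P.

## Known limitations

* No intramuscular/long-acting depot kinetics; oral exposures bound the
  long-acting case for the drug modelled here.
* No mechanism-based (time-dependent) inhibition, transporter induction,
  enterohepatic recirculation, or nonlinear protein binding.
* The gut is two-state with a lumped dissolution curve, not a multi-segment
  transit model; regional solubility and fluid-volume effects are absorbed
  into the calibrated Weibull constants.
* Population physiology is a single reference subject plus log-normal
  multipliers: no age/sex organ scaling, renal impairment, or pediatric
  physiology (an impaired `PhysiologySystem` can be supplied by the user).
* The poor-metabolizer population is defined by a single calibrated
  residual activity (0.5), chosen so the static oracle matches the
  reported PM/NM exposure ratio of 1.41; the true residual-activity
  distribution of the genotype is not modelled.
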