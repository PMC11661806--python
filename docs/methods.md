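# Methods

## The model

`grkin` implements a minimal kinetic model of glucocorticoid receptor (GR)
trafficking.  The receptor occupies seven states — cytoplasmic free (Rc),
cytoplasmic loosely bound (RcG), cytoplasmic tightly bound (RcGt), nuclear
tightly bound (RnGt), activated/DNA-binding-competent (RnGN), nuclear free
(Rn) and nuclear loosely bound (RnG) — connected by two reversible loose
binding steps and six irreversible first-order conversions:

    Rc  ⇌ RcG        equilibrium, dissociation constant Kc (nM)
    RcG → RcGt       k1   cytoplasmic tight-binding conversion
    RcGt→ RnGt       k2   nuclear import (~5 min time constant)
    RnGt→ RnGN       k3   activation
    RnGN→ Rn + G     k4   ligand release (~25 min time constant)
    Rn  → Rc         k5   nuclear export (~9.8 h time constant)
    Rn  ⇌ RnG        equilibrium, dissociation constant Kn (nM)
    RnG → RnGt       k6   nuclear tight-binding conversion

Transcriptional activity is taken proportional to the fraction of receptor
in RnGN (`fRnGN`).  Two qualitative features drive everything: import is
~3500-fold faster than export, so already at picomolar-to-low-nanomolar
ligand the receptor is almost entirely nuclear; and the nuclear recycle
RnGN → Rn → RnG → RnGt → RnGN sustains activation without the receptor ever
leaving the nucleus.

Assumptions inherited from the source model: the six rate constants are
ligand-independent (only Kc and Kn differ between glucocorticoids); the
loose binding steps are fast enough to treat as instantaneous equilibria
(only their equilibrium constants are known); chaperone/cofactor cycles,
receptor synthesis/degradation and downstream transcription dynamics are
outside the model; `Rtot` is a pure scale factor, set to 1.

Units are fixed package-wide: nM, minutes, min⁻¹.

## Steady state and its two Michaelis–Menten limits

With the loose steps at equilibrium (RcG = Rc·G/Kc, RnG = Rn·G/Kn), flux
balance gives the closed-form steady state implemented in
`model.steady_state` (occupancies relative to Rn):

    Rc : k5·Kc/(k1·G)      RcG : k5/k1        RcGt : k5/k2
    Rn : 1                 RnG : G/Kn
    RnGt : (k5 + k6·G/Kn)/k3        RnGN : (k5 + k6·G/Kn)/k4

normalised so the seven occupancies sum to Rtot.  An independent numeric
route (`method="linear"`, a null-space solve of the pooled rate matrix
generated from the reaction edge list) agrees with the closed form to
round-off and serves as the oracle in the tests.

**Infinite-dose maximum.**  As G → ∞ the receptor is confined to the
nuclear recycle loop and

    RnGNmax = 1 / (1 + k4/k3 + k4/k6) = 25/31 ≈ 0.806

independent of the ligand.  All "relative activity" in the package is
fRnGN / RnGNmax.

**High-concentration limit** (receptor 100 % nuclear): the steady state
collapses to `VmaxH·G/(KmH + G)` with

    C = 1 + k6/k3 + k6/k4 = 31        KmH = Kn / C.

This is the regime of ordinary cell-culture EC50 measurements, so the
package infers Kn from a measured transcriptional EC50 (KmT) by
`Kn = KmT·C` (e.g. 5 nM → 155 nM for dexamethasone, 50 nM → 1550 nM for
cortisol, 15 nM → 465 nM for prednisolone/methylprednisolone).  C and KmH
are independent of every cytoplasmic parameter.

**Very-low-concentration limit** (nuclear rebinding negligible,
k6·G/Kn ≪ k5): each receptor transits the whole import/export cycle once
per activation and the dose-response is again Michaelis–Menten, with a tiny
Vmax but an apparent affinity three-to-four orders of magnitude higher than
KmT.  KmL is proportional to Kc and inversely proportional to k1, which is
why sub-picomolar glucocorticoid still produces ~4 % of maximal activity.

**Two published conventions.**  The reference tables print

    VmaxH = 0.769;   D = 31.5,  VmaxL = 0.0317,  KmL = 0.000787 nM (DEX)

whereas the self-consistent asymptotic reduction of the steady state above
gives VmaxH = RnGNmax = 0.8065 and D = 24.9, VmaxL = 0.0401,
KmL = 0.000802 nM.  Both conventions are implemented and exposed through
the `form` argument of `mm_high` / `mm_low`:

* `form="printed"` (default) reproduces the reference constants exactly,
  via
  `VmaxH = 1/(1 + k4/k3 + k4/k6 + k5·(1/k1 + 1/k2 + 1/k3 + 1/k4))`,
  `D = C + k4·(1/k2 + 1/k3 + 1/k6) + k5·(1/k2 + 1/k3 + 1/k4)`,
  `VmaxL = 1/D`, `KmL = Kc·k4·(1 + k4/k3 + k4/k6)/(k1·D)`.
  These forms reproduce the entire printed constant set (including the
  cortisol and methylprednisolone KmL values and the k1 = 1 variant), but
  note that this VmaxH carries a small export-transit correction and is
  therefore *not* cytoplasm-independent, and that VmaxH ≠ RnGNmax.
* `form="derived"` is the internally consistent reduction; it is the form
  whose curves actually track the full model (used in the regime-agreement
  tests), and its VmaxH equals RnGNmax.

The ~5 % (high) and ~25 % (low) discrepancies between the conventions are a
property of the reference constants themselves; the package preserves both
rather than silently reconciling them.  The related outlier: the reference
affinity table lists prednisolone KmL = 0.0044 nM although its Kc equals
methylprednisolone's (KmL ∝ Kc predicts 0.00236 nM for both).  The library
ships the printed value flagged `KmL_suspected_erratum`, and
`consistency_report()` flags the row.

**Validity bands.**  The high-limit curve (derived form) stays within 5 %
of the full model for G ≥ KmH.  The low-limit curve converges to the full
model as G → 0 and is within 5 % below ~0.001·KmT; at 0.01·KmT the
neglected rebinding feed k6·G/Kn is already ≈ 0.01·k6/(C·k5) ≈ 19 % of k5
(a ligand-independent ratio), so the full model sits ~15 % above *any*
Michaelis–Menten curve there.  The often-quoted "valid below about 1 % of
KmT" is therefore an order-of-magnitude statement, not a 5 % band; the
tests assert both the asymptotic agreement and this documented breakdown.

## Time-dependent integration

Dynamics evolve the five pooled quantities (Rc+RcG, RcGt, RnGt, RnGN,
Rn+RnG); the bound/free split inside each pool is algebraic in the
instantaneous G(t).  The right-hand side is generated from the same
reaction edge list as the steady-state solver.  Integration uses LSODA
with rtol 1e-8 / atol 1e-12 (the rates span 1.7e-3–10 min⁻¹), restarting
at profile breakpoints so dose steps are handled exactly rather than
smoothed.  The default output grid is 1 min.  Total receptor is conserved
structurally; trajectories conserve mass to ~1e-9 in the tests.

A step increase in G produces a transient overshoot of fRnGN — the first
synchronized wave of receptor arriving through RnGt decays at k4 into Rn
before the recycle loop equilibrates — which settles to the steady state
within ~100 min.  Since downstream protein responses integrate over many
hours, the daily-average metrics are insensitive to these spikes.

**Cold-chase competition.**  The labeled/unlabeled variant duplicates the
bound states per species; both species share the free pools Rc and Rn and
the loose pools partition in proportion to the species' concentrations
(identical Kc, Kn, k-rates — the species are chemically identical).  With
the packaged protocol (100 nM labeled for 100 min, then a 200-fold
unlabeled excess; the "20 µM" reading of the conflicting source figure
caption) the labeled nuclear signal (RnGt*+RnGN*) plateaus by 100 min and
decays with a ~18 min half-time, inside the 15–30 min band of the measured
~25 min dissociation: after release at k4, relabeling is outcompeted by
the excess, so the decay is governed by k4 (ln 2/k4 ≈ 17 min) plus a small
recycling correction.  With zero chase concentration the variant reduces
to the single-ligand model (verified to 1e-9).

## Synthetic diurnal cortisol

The daily free-cortisol microdialysis samples behind the published curve
are not printed, so the package ships a deterministic synthetic stand-in:
nadir pinned at the printed 1.45 nM at 03:00, a half-cosine rise to the
08:00 peak, and an exponential relaxation (width τ) closing exactly at the
next nadir; the curve is exactly 24 h periodic.  Its two free constants
were calibrated once by `scripts/calibrate_cortisol.py` so that the full
time-dependent model reproduces the two published summary statistics —
day-2 peak relative activity 0.39 and GTQ 0.17 — giving

    peak = 29.96 nM free cortisol,   τ = 224.5 min,

frozen in `grkin.profiles`.  A free-cortisol peak of ~30 nM is
physiologically sensible (total cortisol ~400–550 nM with ~5–10 % free).
What the stand-in does not emulate: ultradian pulsatility, between-subject
variability, and HPA feedback (exogenous suppression of endogenous
cortisol); each drug is evaluated in isolation, without superposing the
endogenous curve.  Tests passing against this curve validate the model
machinery and the two calibrated anchors, not the shape of any individual's
cortisol day.

## Transcription quotient (GTQ)

GTQ = (1/1440)·∫(day 2) fRnGN(t) dt / RnGNmax, trapezoidal quadrature on
the output grid, window = midnight-to-midnight of the day after a burn-in
day (quadrature refinement changes the value by < 1e-4; one burn-in day
leaves day-to-day drift < 1 % for all packaged forcings).  GTQ is 1 for a
saturating constant dose and 0 for none.  Both activity backends are
selectable: the exact time-dependent model (default for the endogenous
cortisol curve) and the pointwise steady-state shortcut (default for drug
regimens, and within 2 % of the exact backend for diurnal-scale forcing,
since receptor equilibration takes minutes while the forcing varies over
hours).

## Pharmacokinetics

DEX and MP: linear two-compartment disposition with first-order oral
absorption, propagated by matrix exponential on a 1-min grid (exact for a
linear system, so dose superposition holds to machine precision).  IV
dexamethasone is dosed as the phosphate ester and converted to DEX
equivalents by molecular weight (392.5/472.4 ≈ 0.83); oral doses are
scaled by F.  Free concentration = fu × central concentration.

Prednisone: oral-only prodrug model with hepatic first-pass conversion
(fraction `first_pass_to_active` of the absorbed dose enters as
prednisolone), continuous free-concentration-driven interconversion
between the species, linear albumin-like binding for prednisone, and
saturable transcortin plus linear binding for prednisolone.  The free
fraction solves the quadratic binding equilibrium
`total = free·(1+N) + Bmax·free/(Kd+free)` and rises from
1/(1+N+Bmax/Kd) ≈ 0.11 at trace levels towards 1/(1+N) ≈ 0.33 at
saturation, which breaks dose-linearity (measurably: >2 % deviation
between 2×5 mg and 10 mg profiles) and keeps the total
prednisolone/prednisone ratio inside the clinically observed 2.7–10 band
across 5–100 mg regimens.

Parameter provenance: the source publication prints only F = 0.59 and
fu = 0.23 (DEX), fu = 0.23 (MP) and the two molecular weights; its full PK
parameterisation (clearances, volumes, absorption and interconversion
rates, transcortin constants) lives in supplementary material that is not
available to this package.  The shipped sets in `data/pk_defaults.yaml`
are literature-plausible placeholders flagged `authoritative: false`,
chosen once so the module is realistic and runnable end to end.
Consequently the published dose-table GTQs are *not* reproduction targets
here: `validate_against_paper()` reports those rows as
"skipped: awaiting supplementary parameters", while everything structural
about regimens (linearity, periodicity, dose monotonicity, b.i.d. ≥ q.d.,
ratio band) is asserted unconditionally.  Dosing clock time defaults to
08:00 (not stated by the source; GTQ is insensitive to it for daily-
periodic regimens).

## Numerical choices and edge cases

* G = 0 returns the all-cytoplasmic state exactly (the closed form's
  1/G term is bypassed); negative concentrations raise.
* Profiles clip at zero after evaluation; periodic profiles are evaluated
  through exact modulo reduction, so f(t) = f(t+period) to 1e-9.
* Solver tolerances rtol 1e-8 / atol 1e-12; state components can
  round-trip as −1e-12 and are clipped by the state container, which
  rejects anything below −1e-9.
* The steady-state linear solve replaces one (redundant) balance row with
  the conservation constraint; no pseudo-inverse is needed.
* Problem sizes: the test suite integrates trajectories of 1–3 simulated
  days at 1–10 min output resolution and evaluates 50-point concentration
  sweeps; the full suite runs in well under a minute.

## Known limitations

* No receptor turnover/downregulation, no chaperone-resolved sub-states,
  no delayed transcription/translation stage, no non-genomic cytosolic
  effects, no stochastic single-molecule variant.
* PK placeholder parameter sets (above); no population variability,
  absorption lag, or enterohepatic recirculation.
* The printed-vs-derived Michaelis–Menten constant discrepancy is
  preserved, not resolved; quantities derived from the low-concentration
  reduction inherit the reference constants' internal ~20 % inconsistency.
* Fitting k1–k6 to new data is out of scope; the rate constants are
  order-of-magnitude estimates and KmL in particular is uncertain through
  its 1/k1 dependence.
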