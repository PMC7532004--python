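# Methods

## The equilibrium gating model

The package analyzes macroscopic GABA_A receptor currents in a three-state
Resting–Open–Desensitized (ROD) equilibrium. The agonist dependence enters
through the saturation factor Γ(x) = ((1 + x/K_C)/(1 + x/K_O))^N, which is
1 at zero agonist and falls to (K_O/K_C)^N at saturation; because the open
state binds agonist more tightly than the resting state (K_C > K_O), a
falling Γ means a rising open probability, P_peak = 1/(1 + LΓ). Sustained
agonist lets receptors equilibrate with the desensitized state, giving
P_ss = 1/(1 + 1/Q + LΓ) and P_des = 1/(1 + Q + Q·LΓ), where Q is the
open/desensitized equilibrium constant (so P_des/P_open = 1/Q always holds
at steady state).

Assumptions, and where they bite:

* **Equilibrium only.** No kinetic information is extracted; rates in the
  trace simulator are free parameters chosen for realistic-looking
  relaxations and do not affect any estimate.
* **Negligible constitutive activity.** Conversions set the zero-agonist
  open probability to zero; a nonzero baseline can be folded into L by the
  caller.
* **Equal open/desensitized agonist affinity.** This makes Q independent of
  agonist concentration and therefore transferable: a Q* estimated at
  saturating agonist can predict occupancies at low agonist. It also reduces
  the predicted binding change to the ratio of (P_open + P_des) sums.
* **Two orthosteric sites (N = 2)** for αβ receptors, user-overridable.

### Inversion path and its numerics

The practical estimator never needs L, K_C, K_O separately: the composite
LΓ = 1/P_peak − 1 comes from the measured peak, then
Q = 1/(1/P_ss − 1 − LΓ) from the measured steady state. Both the composite
path and the full-parameter path (via `GatingParameters`) are exposed.
P_desensitized computed this way equals 1 − P_ss/P_peak, i.e. it depends only
on the sag ratio — which is why the low-agonist occupancies are exactly
recoverable from ratio-consistent inputs even when individually rounded
values are not.

Degenerate inputs: a steady state equal to the peak within relative
tolerance 1e-7 returns Q = +inf (no desensitization) rather than an error;
a steady state exceeding the peak beyond tolerance raises an
inconsistent-measurement error naming both values. The tolerance is kept
well below the smallest sag resolvable in the supported range
(LΓ, Q ≤ 1e3), so the Q round-trip identity holds to 1e-9 across that
range while still absorbing floating-point equality at the boundary.
Occupancy vectors are built with the complement so conservation holds to
1e-12; all probabilities are carried at full precision and rounded to two
decimals only in display fields.

## Trace metrics

Peak is the (optionally moving-average smoothed; default no smoothing, since
oocyte recordings are low-noise) maximum in an application window after
baseline subtraction; steady state is the mean over a late window, defaulting
to the final 10% of the application — both the window fraction and smoothing
are artifact choices, as the acquisition protocol does not prescribe them.
Open probabilities come from normalization to a maximal reference response
(1 mM GABA + 50 µM propofol, defined as P_open = 1); amplitudes exceeding
the reference by ≤ 2% are clipped with a warning (measurement scatter),
larger excesses are errors. Percent desensitization is
100·(1 − I_ss,mod/I_ss,baseline) and is invariant under common rescaling.

## Binding fits

All three fitters are unweighted nonlinear least squares (lmfit,
Levenberg–Marquardt, xtol = ftol = 1e-10), run on concentrations normalized
to their geometric mean so results are invariant under unit rescaling, with
coarse log-grid starting values to avoid local minima:

* **Isotherm** B = B_max·x/(K_d + x); a fitted K_d outside
  [min(conc)/100, max(conc)·100] is reported as a failure rather than a
  number.
* **Hill modulation** E(c) = 100 + (E_max − 100)·cⁿ/(cⁿ + EC50ⁿ), baseline
  anchored at exactly 100% of control (the no-modulator condition defines
  100%); a free-baseline variant is available by flag. E_max < 100 encodes
  inhibition. A fitted effect |E_max − 100| below twice the residual scatter
  is flagged as a degenerate no-effect curve.
* **Time course** B(t) = B0 + (B∞ − B0)(1 − exp(−t/τ)), τ in minutes.

Specific binding is total − nonspecific counts; negative values are retained
with a QC flag so replicate averages stay unbiased. Counts convert to
amounts via dpm = cpm/efficiency and 2.22e12 dpm/Ci. The state-weighted
binding prediction Σ p_state·x/(x + K_d,state) uses the default state
affinities 78.5 µM / 120 nM / 40 nM (resting/open/desensitized).

## Synthetic-data generator

The generator exists so every stage of the pipeline can be validated without
instrument data. It emulates:

* **Per-cell open probabilities** as truncated normals (bounds [0, 1])
  around the closed-form values. Defaults are the benchmark study
  conditions: peak 0.71 with between-cell SD 0.25 over 16 cells;
  steady-state 0.121 with SD 0.033 over 7 control cells; 5 treated cells in
  a paired design (each cell's treated value is its own control scaled by
  the true steroid effect, with the control draw carrying SD 0.013 by
  default).
* **Current traces** from a linear R↔O↔D kinetic scheme whose rate ratios
  are pinned to LΓ and Q, propagated exactly per time step with the matrix
  exponential; equilibria therefore match the closed form (to 1e-6 in the
  oracle tests). The absolute rates (defaults 500 s⁻¹ activation, 0.5 s⁻¹
  desensitization) are arbitrary but separated enough that the transient
  peak matches the closed-form peak within ~0.5%.
* **Assay tables** with multiplicative counting noise (a normal
  approximation to Poisson at the cpm scales used). Isotherm tables are
  generated from a single-site curve with an apparent K_d plus a linear
  nonspecific component, so the noiseless fitter round-trip is exact.
  Modulation tables can be generated either directly from a Hill curve (for
  fitter validation) or mechanistically (below).

### Three-site neurosteroid model

A ligand is a set of site occupancies (intersubunit β(+)/α(−), α-intrasubunit,
β-intrasubunit) with an occupancy constant K_site and saturating efficacy
factors e_L (on L, activation) and e_Q (on Q, desensitization) per site. At
fractional occupancy occ = c/(c + K_site) the applied factor is interpolated
as 1/(1 + occ·(1/e − 1)): 1 at zero occupancy, e at full occupancy, and the
change in 1/L or 1/Q is *linear* in occupancy, so the simulated
binding-enhancement concentration-response has its midpoint at K_site (the
fitted EC50 tracks the site constant). Factors combine multiplicatively
across sites. This mapping is a generator parameterization, not an
experimentally derived law; the qualitative site assignments of the four
built-in presets are:

| ligand | intersubunit | α-intra | β-intra | net effect |
|---|---|---|---|---|
| allopregnanolone (3α5αP) | e_L 0.05 | e_L 0.2 | e_Q 0.59 (K 10× weaker) | PAM + mild desensitizer |
| epi-allopregnanolone (3β5αP) | — | e_Q 0.755 | e_Q 0.755 | desensitizer (NAM) |
| KK148 | neutral | e_Q 0.71 | e_Q 0.71 | desensitizer |
| KK150 | neutral | neutral | neutral | silent site-occluding antagonist |

The 3β5αP per-site factor is calibrated so the combined factor at 3 µM
(site K = 0.25 µM) reproduces the measured Q → Q* shift 0.1459 → 0.0864 at
saturating GABA. This electrophysiological calibration was preferred over
matching the ~195% binding E_max, which a single-Q equilibrium model cannot
reproduce simultaneously (the assays differ in temperature, preparation and
time scale); consequently the mechanistic modulation sweeps for desensitizing
ligands have realistic shape and EC50 but modest amplitude.

### What passing tests do and do not show

The generator matches the analysis model by construction, so recovery tests
demonstrate correctness of the estimators and their noise robustness at the
study's group sizes — not that real receptors obey a single-desensitized-state
equilibrium, that between-cell scatter is truncated-normal, or that steroid
effects combine multiplicatively across sites. Features of real recordings
deliberately not emulated: series-resistance and leak artifacts, slow
solution exchange, rundown, multiple desensitized states, and
agonist-dependent desensitization rates.

## Validation problem sizes

The stochastic recovery study uses 200 Monte-Carlo seeds per quantity:
Q/Q* from simulated cell groups (n = 7 control, n = 5 treated, steady-state
SD 0.033, noise-free peak), Hill curves at 5% multiplicative noise with 6
replicates over a 3 nM–30 µM grid, and time courses at 4 time points
(1, 3, 10, 30 min) with 3-percentage-point additive noise. Recovered means:
Q and Q* within ~2% of generating values, EC50 within 20% in ≥95% of seeds,
τ within ~1%.

## Known limitations

* Single desensitized state; multi-state desensitization and kinetic (rate)
  fitting are out of scope.
* Q transfer across concentrations inherits the equal-affinity assumption;
  if open and desensitized affinities differ materially, low-agonist
  predictions shift.
* The Hill and isotherm fitters assume independent errors; correlated
  plate/membrane effects are not modelled.
* Vendor acquisition formats are not parsed; the interchange format is CSV.
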